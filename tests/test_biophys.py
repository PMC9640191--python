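"""Ground-truth simulator: steady states, synaptic responses, convergence."""

import numpy as np
import pytest

from surroneuron import (
    EventTrain,
    active_point_model,
    excitatory_synapse,
    passive_point_model,
)
from surroneuron.biophys.hh import membrane_current_density, resting_potential
from surroneuron.biophys.model import CompartmentModelSpec
from surroneuron.biophys.point import simulate_point_neuron, steady_state_init


def single_event(g_nS, onset=20.0):
    return EventTrain.from_lists([(onset, 0, g_nS, "exc")])


class TestSteadyStateInit:
    def test_passive_rest_equals_leak_anchor(self, passive_model, passive_init):
        assert passive_init.v == pytest.approx(-70.0, abs=1e-9)

    def test_active_rest_equals_root_found_fixed_point(self, active_model, active_init):
        v_root = resting_potential(active_model)
        assert active_init.v == pytest.approx(v_root, abs=1e-6)
        assert abs(membrane_current_density(active_init.v, active_model)) < 1e-9

    def test_zero_channel_densities_rest_at_weighted_leak_reversal(self):
        model = active_point_model(gna_S_cm2=0.0, gk_S_cm2=0.0)
        expected = model.leak_S_cm2()[1]
        init = steady_state_init(model)
        assert init.v == pytest.approx(expected, abs=1e-6)

    def test_event_free_trace_is_flat_at_rest(self, passive_model, passive_init):
        tr = simulate_point_neuron(passive_model, [], EventTrain(), 500.0, init=passive_init)
        assert np.allclose(tr.v, -70.0, atol=1e-9)

    def test_post_transient_return_to_rest(self, active_model, active_init):
        tr = simulate_point_neuron(
            active_model, [excitatory_synapse()], single_event(2.0), 1500.0,
            init=active_init,
        )
        assert abs(tr.v[-1] - active_init.v) < 0.01


class TestSynapticResponse:
    def test_epsp_peak_matches_fine_dt_oracle(self, passive_model, passive_init):
        """Single 2.5 nS excitatory event: peak amplitude within 0.5% of a
        brute-force reference integration at dt = 1 us."""
        syn = [excitatory_synapse()]
        coarse = simulate_point_neuron(
            passive_model, syn, single_event(2.5), 60.0, init=passive_init, fine=True
        )
        fine = simulate_point_neuron(
            passive_model, syn, single_event(2.5), 60.0, init=passive_init,
            fine=True, internal_dt_ms=0.001,
        )
        a_coarse = coarse.v.max() - coarse.v[0]
        a_fine = fine.v.max() - fine.v[0]
        assert a_coarse == pytest.approx(a_fine, rel=5e-3)

    def test_dt_doubling_changes_subthreshold_peak_below_one_percent(
        self, active_model, active_init
    ):
        syn = [excitatory_synapse()]
        kwargs = dict(init=active_init)
        a = simulate_point_neuron(active_model, syn, single_event(2.0), 80.0, **kwargs)
        b = simulate_point_neuron(
            active_model, syn, single_event(2.0), 80.0, internal_dt_ms=0.05, **kwargs
        )
        pa = a.v.max() - a.v[0]
        pb = b.v.max() - b.v[0]
        assert abs(pa - pb) / pa < 0.01

    def test_subthreshold_amplitudes_grow_with_quantal_size(
        self, active_model, active_init
    ):
        syn = [excitatory_synapse()]
        amps = []
        for g in (0.5, 1.0, 1.5, 2.0, 2.5):
            tr = simulate_point_neuron(
                active_model, syn, single_event(g), 100.0, init=active_init
            )
            amps.append(tr.v.max() - tr.v[0])
        assert np.all(np.diff(amps) > 0)

    def test_sweep_produces_one_ap_beyond_subthreshold_range(
        self, active_model, active_init
    ):
        syn = [excitatory_synapse()]
        sub = simulate_point_neuron(active_model, syn, single_event(3.5), 150.0, init=active_init)
        supra = simulate_point_neuron(active_model, syn, single_event(3.6), 150.0, init=active_init)
        assert sub.v.max() < 0.0
        assert supra.v.max() > 0.0

    def test_event_outside_window_raises(self, passive_model, passive_init):
        with pytest.raises(ValueError, match="within the simulation window"):
            simulate_point_neuron(
                passive_model, [excitatory_synapse()], single_event(1.0, onset=200.0),
                100.0, init=passive_init,
            )


class TestKdrShift:
    """A rightward (depolarizing) shift of the delayed rectifier reduces K+
    activation, so responses above its activation range depolarize relative
    to control, and a leftward shift does the opposite; below the activation
    range the shift has no measurable effect."""

    @pytest.fixture(scope="class")
    def shifted_traces(self):
        out = {}
        train = EventTrain.from_lists(
            [(t, 0, 3.0, "exc") for t in (20.0, 28.0, 36.0, 44.0)]
        )
        for shift in (-10.0, 0.0, 10.0):
            model = active_point_model(kdr_shift=shift)
            tr = simulate_point_neuron(
                model, [excitatory_synapse()], train, 120.0,
                init=steady_state_init(model),
            )
            out[shift] = tr
        return out

    def test_sign_of_difference_above_activation_threshold(self, shifted_traces):
        control = shifted_traces[0.0].v
        mask = control > -63.0  # clearly above the -67 mV activation region
        assert mask.sum() > 5
        assert np.mean(shifted_traces[10.0].v[mask] - control[mask]) > 0
        assert np.mean(shifted_traces[-10.0].v[mask] - control[mask]) < 0

    def test_no_effect_well_below_activation_threshold(self, shifted_traces):
        control = shifted_traces[0.0].v
        mask = control < -69.0
        if mask.sum():
            assert np.max(np.abs(shifted_traces[10.0].v[mask] - control[mask])) < 0.3


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length_um=-1.0),
            dict(cm_uF_cm2=0.0),
            dict(gna_S_cm2=-0.1),
            dict(e_na=200.0),
        ],
    )
    def test_invalid_compartment_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CompartmentModelSpec(**kwargs)
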
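"""Metrics: explained variance, spike matching, rate-model fits, I/V."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from surroneuron.evaluation import (
    explained_variance,
    fit_firing_models,
    iv_summary,
    logistic4,
    match_spike_trains,
    spike_match,
)
from surroneuron.trace import VoltageTrace


class TestExplainedVariance:
    def test_perfect_prediction_gives_one(self):
        x = np.random.default_rng(0).normal(size=200)
        assert explained_variance(x, x) == pytest.approx(1.0)

    def test_mean_prediction_gives_zero(self):
        x = np.random.default_rng(0).normal(size=200)
        assert explained_variance(np.full_like(x, x.mean()), x) == pytest.approx(0.0)

    def test_white_noise_closed_form(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(0, 2.0, 200000)
        sigma = 0.5
        pred = truth + rng.normal(0, sigma, truth.shape)
        expected = 1.0 - sigma**2 / np.var(truth)
        assert explained_variance(pred, truth) == pytest.approx(expected, abs=5e-3)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            explained_variance(np.zeros(10), np.ones(10))

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(min_value=0.1, max_value=50.0),
        offset=st.floats(min_value=-100.0, max_value=100.0),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_invariant_under_common_affine_rescaling(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        truth = rng.normal(size=100)
        pred = truth + rng.normal(0, 0.3, 100)
        a = explained_variance(pred, truth)
        b = explained_variance(scale * pred + offset, scale * truth + offset)
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)


class TestSpikeMatch:
    def test_identical_trains_perfect_scores(self):
        t = np.array([50.0, 150.0, 400.0])
        r = match_spike_trains(t, t)
        assert r.precision == r.recall == 1.0
        assert np.all(r.shifts_ms == 0)

    def test_empty_prediction_flagged(self):
        r = match_spike_trains(np.array([]), np.array([100.0]))
        assert r.recall == 0.0
        assert r.precision == 0.0
        assert r.degenerate

    def test_empty_truth_flagged_with_unit_recall(self):
        r = match_spike_trains(np.array([100.0]), np.array([]))
        assert r.recall == 1.0
        assert r.degenerate

    def test_hand_enumerated_case(self):
        r = match_spike_trains(np.array([103.0, 290.0]), np.array([100.0, 200.0]))
        assert (r.tp, r.fp, r.fn) == (1, 1, 1)
        assert r.precision == r.recall == 0.5
        assert r.shifts_ms.tolist() == [3.0]

    def test_each_true_spike_matched_at_most_once(self):
        r = match_spike_trains(np.array([99.0, 101.0]), np.array([100.0]))
        assert r.tp == 1
        assert r.fp == 1

    def test_detects_spikes_on_traces(self):
        v = np.full(300, -70.0)
        v[[50, 120]] = 25.0
        r = spike_match(VoltageTrace(v=v), VoltageTrace(v=v))
        assert r.tp == 2

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=500))
    def test_symmetry_swaps_precision_and_recall(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 1000, rng.integers(0, 15)))
        b = np.sort(rng.uniform(0, 1000, rng.integers(0, 15)))
        assume(len(a) > 0 and len(b) > 0)  # rate conventions differ when empty
        r1 = match_spike_trains(a, b)
        r2 = match_spike_trains(b, a)
        assert r1.tp == r2.tp
        assert r1.precision == pytest.approx(r2.recall)
        assert r1.recall == pytest.approx(r2.precision)


class TestFiringModels:
    def test_line_data_prefers_linear_model(self):
        x = np.linspace(0, 10, 20)
        y = 2.0 + 0.5 * x
        fit = fit_firing_models(x, y)
        assert fit.winner == "linear"
        assert fit.linear == (pytest.approx(2.0), pytest.approx(0.5))

    def test_logistic_data_recovers_midpoint(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 100, 60)
        true = (0.0, 40.0, 55.0, -8.0)  # A1, A2, x0, dx (increasing curve)
        y = logistic4(x, *true) + rng.normal(0, 0.5, x.shape)
        fit = fit_firing_models(x, y)
        assert fit.winner == "logistic"
        assert fit.logistic[2] == pytest.approx(55.0, abs=2.0)

    def test_fitted_logistic_passes_through_midpoint_identity(self):
        x = np.linspace(0, 100, 40)
        y = logistic4(x, 5.0, 45.0, 50.0, -10.0)
        fit = fit_firing_models(x, y)
        a1, a2, x0, dx = fit.logistic
        assert logistic4(x0, *fit.logistic) == pytest.approx((a1 + a2) / 2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_firing_models([1, 2, 3], [1, 2, 3])


class TestIvSummary:
    def _rc_traces(self, gs, r_mV_per_nS=2.0, rest=-70.0):
        """Analytic linear toy: peak amplitude exactly r * g."""
        traces = []
        for g in gs:
            v = np.full(100, rest)
            v[30] = rest + r_mV_per_nS * g
            traces.append(VoltageTrace(v=v))
        return traces

    def test_slope_matches_closed_form_linear_toy(self):
        gs = np.arange(0.1, 2.01, 0.1)
        summary = iv_summary(gs, self._rc_traces(gs))
        assert summary.slope_mV_per_nS == pytest.approx(2.0, rel=1e-9)
        assert summary.intercept_mV == pytest.approx(0.0, abs=1e-9)
        assert summary.pearson_r == pytest.approx(1.0)

    def test_all_subthreshold_sweep_reports_absent_threshold(self):
        gs = np.arange(0.1, 1.01, 0.1)
        summary = iv_summary(gs, self._rc_traces(gs))
        assert summary.ap_threshold_mV is None

    def test_threshold_is_peak_of_largest_subthreshold_trial(self):
        gs = np.arange(0.5, 5.01, 0.5)
        traces = self._rc_traces(gs, r_mV_per_nS=4.0)
        traces[-1].v[30] = 30.0  # largest trial fires
        summary = iv_summary(gs, traces)
        assert summary.ap_threshold_mV == pytest.approx(-70.0 + 4.0 * 4.5)

    def test_rc_oracle_on_simulated_passive_sweep(self, passive_model, passive_init):
        """Small-conductance sweep on the passive membrane: the fitted slope
        equals the closed-form RC peak response per unit conductance."""
        from surroneuron import excitatory_synapse
        from surroneuron.biophys.point import simulate_point_neuron
        from surroneuron.events import EventTrain
        from scipy.optimize import brentq

        gs = np.arange(0.02, 0.21, 0.02)
        traces = []
        for g in gs:
            ev = EventTrain.from_lists([(20.0, 0, float(g), "exc")])
            traces.append(
                simulate_point_neuron(passive_model, [excitatory_synapse()], ev,
                                      100.0, init=passive_init)
            )
        summary = iv_summary(gs, traces)
        # closed form: linearized RC membrane driven by a unit alpha
        # conductance transient with fixed driving force E - v_rest
        g_l, _, *_ = passive_model.membrane_conductances_uS()
        c = passive_model.c_nF
        tau_m = c / g_l  # ms
        tau_s = 2.0
        drive = 70.0  # mV driving force at rest (E_exc = 0)

        def response(t):
            # Delta V(t) for a 1-nS alpha conductance (peak 1e-3 uS):
            # (D w e / C tau_s) * e^(-t/tau_m) * (1 - (1 + k t) e^(-k t)) / k^2
            # with k = 1/tau_s - 1/tau_m (convolution of the alpha transient
            # with the membrane's exponential kernel)
            w = 1e-3
            a = drive * w * np.e / (c * tau_s)
            k = 1.0 / tau_s - 1.0 / tau_m
            if abs(k) < 1e-12:
                return a * np.exp(-t / tau_m) * t * t / 2.0
            return a * np.exp(-t / tau_m) * (1.0 - (1.0 + k * t) * np.exp(-k * t)) / k**2

        ts = np.linspace(0.1, 20.0, 4000)
        peak_per_nS = max(response(t) for t in ts)
        assert summary.slope_mV_per_nS == pytest.approx(peak_per_nS, rel=0.03)
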
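"""Voltage-dependent NMDA gating and the paired-pulse coincidence protocol.

The NMDA conductance is an alpha transient multiplied by a Boltzmann function
of the instantaneous membrane potential.  The gate is oriented so that it
opens with depolarization (relief of the voltage-dependent block): at
hyperpolarized potentials the scale tends to A2, at depolarized potentials to
A1, and at v = x0 it equals (A1 + A2) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from surroneuron.biophys.model import (
    CompartmentModelSpec,
    active_point_model,
    ampa_synapse,
    nmda_synapse,
)
from surroneuron.biophys.point import simulate_point_neuron, steady_state_init
from surroneuron.events import EventTrain


def nmda_gate(v, boltzmann: Tuple[float, float, float, float]):
    """Boltzmann scale of the NMDA conductance at membrane potential ``v`` (mV).

    Returns A2 + (A1 - A2) / (1 + exp((x0 - v) / dx)); increases with
    depolarization for A1 > A2.
    """
    a1, a2, x0, dx = boltzmann
    if dx == 0:
        raise ValueError("boltzmann dx must be nonzero")
    v = np.asarray(v, dtype=float)
    arg = np.clip((x0 - v) / dx, -700.0, 700.0)
    out = a2 + (a1 - a2) / (1.0 + np.exp(arg))
    return float(out) if out.ndim == 0 else out


@dataclass
class CoincidenceResult:
    isi_ms: float
    compound_peak_mV: float
    unitary_peak_mV: float
    linear_sum_mV: float
    spiked: bool


def _peak_amplitude(trace, baseline):
    return float(np.max(trace.v) - baseline)


def simulate_coincidence_protocol(
    model: Optional[CompartmentModelSpec] = None,
    ampa_only: bool = False,
    isi_ms: float = 0.0,
    weight_nS: float = 1.2,
    nmda_weight_nS: Optional[float] = 3.0,
    t0_ms: float = 50.0,
    duration_ms: float = 200.0,
) -> CoincidenceResult:
    """Two excitatory events separated by ``isi_ms`` on an AMPA or AMPA+NMDA cell.

    Returns the compound EPSP peak, the unitary peak, their linear sum and a
    spike flag.  With NMDA present, near-coincident inputs depolarize the cell
    enough to open the voltage gate and boost the compound response beyond
    linear summation; AMPA alone stays at or below the linear sum.
    """
    if model is None:
        model = active_point_model()
    if nmda_weight_nS is None:
        nmda_weight_nS = weight_nS
    synapses = [ampa_synapse()] if ampa_only else [ampa_synapse(), nmda_synapse()]
    init = steady_state_init(model)

    def run(onsets):
        events = []
        for t in onsets:
            events.append((t, 0, weight_nS, "exc"))
            if not ampa_only:
                events.append((t, 1, nmda_weight_nS, "exc"))
        train = EventTrain.from_lists(events)
        return simulate_point_neuron(model, synapses, train, duration_ms, init=init)

    unitary = run([t0_ms])
    compound = run([t0_ms, t0_ms + abs(isi_ms)])
    baseline = float(unitary.v[0])
    unit_peak = _peak_amplitude(unitary, baseline)
    comp_peak = _peak_amplitude(compound, baseline)
    spiked = bool(np.max(compound.v) >= 0.0)
    return CoincidenceResult(
        isi_ms=isi_ms,
        compound_peak_mV=comp_peak,
        unitary_peak_mV=unit_peak,
        linear_sum_mV=2.0 * unit_peak,
        spiked=spiked,
    )
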
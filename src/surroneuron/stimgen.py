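"""Seeded stimulus-protocol generators.

All generators are pure functions of their parameters and seed, produce
events on a 1-ms onset grid (matching the 1 kHz channel encoding), and
round-trip losslessly through the event-table CSV format.

Default quantal sizes follow the reference point-neuron synapses: 2.5 nS
excitatory (tau 2 ms, 0 mV) and 8 nS inhibitory (tau 1 ms, -90 mV), delivered
at an 8:3 excitatory:inhibitory count ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from surroneuron.events import EventTrain, EXC, INH

DEFAULT_EXC_WEIGHT_NS = 2.5
DEFAULT_INH_WEIGHT_NS = 8.0
DEFAULT_EI_RATIO = (8, 3)


@dataclass(frozen=True)
class ProtocolSpec:
    """Named protocol description, used by the CLI front end."""

    name: str
    duration_ms: float
    seed: int
    parameters: dict = field(default_factory=dict)


def split_counts(n_total: int, ei_ratio: Tuple[int, int]) -> Tuple[int, int]:
    """Split ``n_total`` events by the E:I ratio; the remainder after the
    proportional (floor) inhibitory share goes to the excitatory side."""
    e, i = ei_ratio
    if e <= 0 or i <= 0:
        raise ValueError("ei_ratio components must be positive")
    n_inh = int(n_total * i / (e + i))
    return n_total - n_inh, n_inh


def random_train(
    duration_ms: float,
    n_total: int,
    ei_ratio: Tuple[int, int] = DEFAULT_EI_RATIO,
    seed: int = 0,
    exc_weight_nS: float = DEFAULT_EXC_WEIGHT_NS,
    inh_weight_nS: float = DEFAULT_INH_WEIGHT_NS,
    exc_sites: Sequence[int] = (0,),
    inh_sites: Sequence[int] = (1,),
) -> EventTrain:
    """Uniform-random event onsets with counts split by the E:I ratio.

    ``exc_sites`` / ``inh_sites`` are the synapse ids events are assigned to
    (uniformly at random when several are given); the defaults address one
    excitatory (id 0) and one inhibitory (id 1) synapse.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_exc, n_inh = split_counts(n_total, ei_ratio)
    if n_total == 0:
        return EventTrain()
    onset_grid = int(duration_ms)
    onsets = rng.integers(0, onset_grid, size=n_exc + n_inh).astype(float)
    sites = np.concatenate(
        [
            rng.choice(np.asarray(exc_sites, dtype=np.int64), size=n_exc),
            rng.choice(np.asarray(inh_sites, dtype=np.int64), size=n_inh),
        ]
    )
    weights = np.concatenate([np.full(n_exc, exc_weight_nS), np.full(n_inh, inh_weight_nS)])
    polarity = np.array([EXC] * n_exc + [INH] * n_inh, dtype=object)
    return EventTrain(onsets, sites, weights, polarity)


def quantal_sweep(
    g_min_nS: float = 0.1,
    g_max_nS: float = 3.5,
    step_nS: float = 0.1,
    onset_ms: float = 20.0,
    synapse_id: int = 0,
) -> List[EventTrain]:
    """One single-excitatory-event train per conductance in the sweep."""
    if g_min_nS > g_max_nS or step_nS <= 0:
        raise ValueError("need g_min <= g_max and positive step")
    n = int(round((g_max_nS - g_min_nS) / step_nS)) + 1
    weights = g_min_nS + step_nS * np.arange(n)
    return [
        EventTrain.from_lists([(onset_ms, synapse_id, float(w), EXC)]) for w in weights
    ]


def paired_pulse_protocols(
    isi_min_ms: float = 2.0,
    isi_max_ms: float = 10.0,
    isi_step_ms: float = 1.0,
    n_pulses: int = 2,
    weight_nS: float = DEFAULT_EXC_WEIGHT_NS,
    onset_ms: float = 20.0,
    synapse_id: int = 0,
) -> List[EventTrain]:
    """Equal-weight excitatory pulse trains, one per inter-stimulus interval."""
    if isi_min_ms <= 0:
        raise ValueError("ISIs must be positive")
    n_isi = int(round((isi_max_ms - isi_min_ms) / isi_step_ms)) + 1
    isis = isi_min_ms + isi_step_ms * np.arange(n_isi)
    protocols = []
    for isi in isis:
        onsets = onset_ms + isi * np.arange(n_pulses)
        protocols.append(
            EventTrain.from_lists([(float(t), synapse_id, weight_nS, EXC) for t in onsets])
        )
    return protocols


def variable_weight_train(
    duration_ms: float,
    n_total: int,
    mean_nS: float = 2.5,
    variance_nS2: float = 0.001,
    seed: int = 0,
    ei_ratio: Tuple[int, int] = DEFAULT_EI_RATIO,
    inh_weight_nS: float = DEFAULT_INH_WEIGHT_NS,
) -> EventTrain:
    """Random train whose excitatory weights are drawn from a normal
    distribution (negative draws clipped to zero)."""
    if mean_nS <= 0:
        raise ValueError("mean weight must be positive")
    rng = np.random.default_rng(seed)
    train = random_train(
        duration_ms, n_total, ei_ratio, seed=rng.integers(2**31), inh_weight_nS=inh_weight_nS
    )
    exc_mask = train.polarity == EXC
    draws = rng.normal(mean_nS, np.sqrt(variance_nS2), size=int(exc_mask.sum()))
    train.weight_nS[exc_mask] = np.clip(draws, 0.0, None)
    return train


def ei_grid(
    rates_hz: Sequence[float],
    ratios: Sequence[Tuple[int, int]],
    duration_ms: float = 1000.0,
    n_repeats: int = 1,
    seed: int = 0,
) -> List[dict]:
    """One random train per (ratio, rate, repeat) cell of the E/I grid.

    ``rates_hz`` are total synaptic event rates; event counts are
    proportional to rate and duration.  Returns a flat list of records with
    keys ratio, rate_hz, repeat, train.
    """
    if any(r <= 0 for r in rates_hz):
        raise ValueError("rates must be positive")
    root = np.random.default_rng(seed)
    grid = []
    for ratio in ratios:
        for rate in rates_hz:
            for rep in range(n_repeats):
                n_total = int(round(rate * duration_ms / 1000.0))
                train = random_train(
                    duration_ms, n_total, ratio, seed=int(root.integers(2**31))
                )
                grid.append(
                    {"ratio": tuple(ratio), "rate_hz": float(rate), "repeat": rep, "train": train}
                )
    return grid
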
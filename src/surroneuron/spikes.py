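"""Spike detection on sampled voltage traces.

A spike is an upward crossing of the detection level (0 mV by default); its
time is the local maximum before the trace falls back below the level.
"""

from __future__ import annotations

import numpy as np


def detect_spikes(v: np.ndarray, threshold_mV: float = 0.0) -> np.ndarray:
    """Indices of spike peaks (sample index of the local maximum of each
    suprathreshold excursion)."""
    v = np.asarray(v, dtype=float)
    above = v >= threshold_mV
    if not above.any():
        return np.empty(0, dtype=np.int64)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(v)]])
    peaks = [int(s + np.argmax(v[s:e])) for s, e in zip(starts, ends)]
    return np.asarray(peaks, dtype=np.int64)


def spike_times_ms(v: np.ndarray, dt_ms: float = 1.0, threshold_mV: float = 0.0) -> np.ndarray:
    return detect_spikes(v, threshold_mV) * dt_ms


def ap_threshold_dvdt(
    v: np.ndarray, dt_ms: float, criterion_mV_per_ms: float = 20.0
) -> float:
    """Voltage at the first point where dV/dt reaches the criterion before a
    spike (the conventional dV/dt threshold estimate); NaN without a spike."""
    peaks = detect_spikes(v)
    if len(peaks) == 0:
        return float("nan")
    dv = np.diff(v) / dt_ms
    pre = dv[: peaks[0]]
    hits = np.flatnonzero(pre >= criterion_mV_per_ms)
    if len(hits) == 0:
        return float("nan")
    return float(v[hits[0]])
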
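"""Teacher-forced and autoregressive (continuous self-reliant) prediction.

In autoregressive mode the model is initialized with a ground-truth history
window; afterwards each predicted sample is appended to the rolling input
(in normalized space, fed back unmodified) while the synaptic-input channels
always come from the scheduled protocol, never from predictions.  Predicted
ionic currents, when present, are fed back on their own channels exactly
like voltage.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from surroneuron.architectures import SurrogateModel
from surroneuron.data import WindowedDataset, _event_channels
from surroneuron.events import EventTrain
from surroneuron.spikes import detect_spikes
from surroneuron.trace import VoltageTrace


def teacher_forced(model: SurrogateModel, ds: WindowedDataset,
                   indices: Optional[np.ndarray] = None,
                   batch_size: int = 4096) -> np.ndarray:
    """One-step predictions for every window (no feedback); shape (N, T)."""
    if ds.n_channels != model.spec.input_channels:
        raise ValueError(
            f"dataset has {ds.n_channels} channels, model expects {model.spec.input_channels}"
        )
    if indices is None:
        indices = np.arange(len(ds))
    outs = []
    for start in range(0, len(indices), batch_size):
        X, _ = ds.gather(indices[start : start + batch_size])
        outs.append(model.net.forward(X, training=False))
    return np.concatenate(outs)


def _normalized_timeline(model, trace, events, horizon_ms, synapse_channels):
    """Channel matrix over [0, len(trace) + horizon): ground truth history,
    scheduled event channels, zeros where predictions will be written."""
    norm = model.norm
    if norm is None:
        raise ValueError("model has no normalization contract")
    window = model.spec.window
    if len(trace) < window:
        raise ValueError(f"initial trace must provide at least {window} samples")
    n_total = len(trace) + int(round(horizon_ms))
    ev_mat, ev_names = _event_channels(events, n_total, synapse_channels)
    names = ["v"] + ev_names
    cols = [np.zeros((n_total, 1)), ev_mat * norm.g_scale]
    current_names = []
    if model.channel_names and "i_na" in model.channel_names:
        current_names = ["i_na", "i_k"]
        cols.append(np.zeros((n_total, 2)))
    names += current_names
    M = np.concatenate(cols, axis=1)
    if M.shape[1] != model.spec.input_channels:
        raise ValueError(
            f"channel mismatch: built {M.shape[1]}, model expects {model.spec.input_channels}"
        )
    # ground-truth history, spike-standardized like the training corpus
    v = trace.v.copy()
    peaks = detect_spikes(v)
    v[peaks] = norm.spike_peak_mV
    M[: len(trace), 0] = np.clip(norm.normalize_v(v), 0.0, 1.0)
    if current_names:
        if trace.i_na is None or norm.i_scale is None:
            raise ValueError("current channels requested but unavailable")
        M[: len(trace), names.index("i_na")] = trace.i_na / norm.i_scale[0]
        M[: len(trace), names.index("i_k")] = trace.i_k / norm.i_scale[1]
    return M, names


def autoregressive_many(
    model: SurrogateModel,
    runs: Sequence[Tuple[VoltageTrace, EventTrain]],
    horizon_ms: float,
    synapse_channels: Optional[int] = None,
) -> List[VoltageTrace]:
    """Run several autoregressive predictions as one batched rollout.

    Each run supplies its initialization trace (>= one window of ground
    truth) and the event schedule over the whole timeline.  Returns one
    denormalized trace of ``horizon_ms`` samples per run.
    """
    window = model.spec.window
    horizon = int(round(horizon_ms))
    mats = []
    starts = []
    for trace, events in runs:
        M, names = _normalized_timeline(model, trace, events, horizon_ms, synapse_channels)
        mats.append(M)
        starts.append(len(trace))
    if len(set(starts)) != 1:
        raise ValueError("all runs must share the initialization length")
    start = starts[0]
    batch = np.stack(mats)  # (R, n_total, C)
    out_w = model.spec.output_width
    cur_cols = [names.index(n) for n in ("i_na", "i_k") if n in names][: max(out_w - 1, 0)]
    for t in range(start, start + horizon):
        X = batch[:, t - window : t, :]
        y = model.net.forward(X, training=False)
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y).all(axis=1))[0])
            raise RuntimeError(f"non-finite prediction at step {t - start} (run {bad})")
        batch[:, t, 0] = y[:, 0]
        for j, c in enumerate(cur_cols):
            batch[:, t, c] = y[:, j + 1]
    norm = model.norm
    traces = []
    for r in range(len(runs)):
        v = norm.denormalize_v(batch[r, start : start + horizon, 0])
        i_na = i_k = None
        if cur_cols and norm.i_scale:
            i_na = batch[r, start : start + horizon, cur_cols[0]] * norm.i_scale[0]
            i_k = batch[r, start : start + horizon, cur_cols[1]] * norm.i_scale[1]
        traces.append(VoltageTrace(v=v, dt_sample=1.0, i_na=i_na, i_k=i_k))
    return traces


def autoregressive(
    model: SurrogateModel,
    init_trace: VoltageTrace,
    events: EventTrain,
    horizon_ms: float,
    synapse_channels: Optional[int] = None,
) -> VoltageTrace:
    """Single continuous self-reliant prediction (see autoregressive_many)."""
    return autoregressive_many(model, [(init_trace, events)], horizon_ms, synapse_channels)[0]
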
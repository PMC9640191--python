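"""Supervised windowing of traces and events.

Each training example is a 64-sample history window of membrane potential
plus synaptic-input channels (and optionally ionic currents); the target is
the next sample of the predicted channels.  Voltage is scaled to [0, 1] from
fixed physiological bounds (-90 to +40 mV) so the inverse map is
model-independent; detected spike-peak samples are standardized to +40 mV
before scaling (the 1 kHz sampling truncates action-potential peaks at
variable heights, which would otherwise present inconsistent targets).
Splits are contiguous 80/10/10 blocks per trace, avoiding the train/test
leakage that shuffled overlapping windows would produce.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from surroneuron.events import EventTrain, EXC
from surroneuron.spikes import detect_spikes
from surroneuron.trace import VoltageTrace

logger = logging.getLogger(__name__)

TRAIN, VAL, TEST = 0, 1, 2
CURRICULUM_ORDER = ("resting", "subthreshold", "suprathreshold")


@dataclass
class NormalizationParams:
    """Invertible scaling contract shared by datasets and models."""

    v_lo: float = -90.0
    v_hi: float = 40.0
    spike_peak_mV: float = 40.0
    g_scale: float = 0.1
    i_scale: Optional[List[float]] = None  # per current channel, fitted on train

    def normalize_v(self, v):
        return (np.asarray(v) - self.v_lo) / (self.v_hi - self.v_lo)

    def denormalize_v(self, x):
        return np.asarray(x) * (self.v_hi - self.v_lo) + self.v_lo

    def to_dict(self) -> dict:
        return {
            "v_lo": self.v_lo,
            "v_hi": self.v_hi,
            "spike_peak_mV": self.spike_peak_mV,
            "g_scale": self.g_scale,
            "i_scale": self.i_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(**d)


def _event_channels(
    events: EventTrain, n_samples: int, synapse_channels: Optional[int]
) -> Tuple[np.ndarray, List[str]]:
    """Encode events on the sample grid: the channel holds the quantal
    conductance at the onset sample and zero elsewhere."""
    if synapse_channels is None:
        mat = np.zeros((n_samples, 2))
        names = ["exc", "inh"]
        for onset, w, pol in zip(events.onset_ms, events.weight_nS, events.polarity):
            s = int(round(onset))
            if 0 <= s < n_samples:
                mat[s, 0 if pol == EXC else 1] += w
    else:
        mat = np.zeros((n_samples, synapse_channels))
        names = [f"syn{i}" for i in range(synapse_channels)]
        for onset, sid, w in zip(events.onset_ms, events.synapse_id, events.weight_nS):
            s = int(round(onset))
            if 0 <= s < n_samples:
                mat[s, sid] += w
    return mat, names


@dataclass
class WindowedDataset:
    """Windows are assembled lazily from per-trace channel series, so the
    201-channel format does not require materializing N x 64 x 201 arrays."""

    series: List[np.ndarray]  # per trace: (n_samples, C)
    channel_names: List[str]
    window: int
    target_channels: List[int]
    index: np.ndarray  # (N, 2): trace id, target sample
    split: np.ndarray  # (N,) in {TRAIN, VAL, TEST}
    norm: Optional[NormalizationParams] = None
    normalized: bool = False
    n_clipped: int = 0

    def __len__(self) -> int:
        return len(self.index)

    @property
    def n_channels(self) -> int:
        return self.series[0].shape[1]

    def gather(self, indices: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        indices = np.asarray(indices)
        n = len(indices)
        X = np.empty((n, self.window, self.n_channels), dtype=np.float32)
        y = np.empty((n, len(self.target_channels)), dtype=np.float32)
        tc = self.target_channels
        for k, idx in enumerate(indices):
            trace_id, t = self.index[idx]
            s = self.series[trace_id]
            X[k] = s[t - self.window : t]
            y[k] = s[t, tc]
        return X, y

    def split_indices(self, which: int) -> np.ndarray:
        return np.flatnonzero(self.split == which)

    @property
    def inputs(self) -> np.ndarray:
        return self.gather(np.arange(len(self)))[0]

    @property
    def targets(self) -> np.ndarray:
        return self.gather(np.arange(len(self)))[1]


def make_windows(
    pairs: Sequence[Tuple[VoltageTrace, EventTrain]],
    window: int = 64,
    include_currents: bool = False,
    synapse_channels: Optional[int] = None,
    split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> WindowedDataset:
    """Build a windowed dataset from (trace, events) pairs.

    Channels are ordered [v, exc, inh] (or [v, syn0..synK-1] in the
    per-synapse format), followed by [i_na, i_k] when currents are included;
    current channels are also targets in that case.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], VoltageTrace):
        pairs = [pairs]
    series = []
    names: List[str] = []
    idx_rows = []
    split_rows = []
    for trace_id, (trace, events) in enumerate(pairs):
        if abs(trace.dt_sample - 1.0) > 1e-9:
            raise ValueError("windowing expects 1 kHz traces")
        n = len(trace)
        if n < window + 1:
            raise ValueError(f"trace of length {n} is shorter than window + 1")
        ev_mat, ev_names = _event_channels(events, n, synapse_channels)
        cols = [trace.v[:, None], ev_mat]
        names = ["v"] + ev_names
        if include_currents:
            if trace.i_na is None or trace.i_k is None:
                raise ValueError("include_currents requires recorded I_Na and I_K")
            cols += [trace.i_na[:, None], trace.i_k[:, None]]
            names += ["i_na", "i_k"]
        mat = np.concatenate(cols, axis=1)
        series.append(mat)
        targets_t = np.arange(window, n)
        idx_rows.append(np.stack([np.full(n - window, trace_id), targets_t], axis=1))
        n_win = n - window
        n_train = int(round(split_fractions[0] * n_win))
        n_val = int(round(split_fractions[1] * n_win))
        s = np.full(n_win, TEST, dtype=np.int8)
        s[:n_train] = TRAIN
        s[n_train : n_train + n_val] = VAL
        split_rows.append(s)
    target_channels = [0]
    if include_currents:
        target_channels = [0, names.index("i_na"), names.index("i_k")]
    return WindowedDataset(
        series=series,
        channel_names=names,
        window=window,
        target_channels=target_channels,
        index=np.concatenate(idx_rows).astype(np.int64),
        split=np.concatenate(split_rows),
    )


def normalize(
    ds: WindowedDataset, params: Optional[NormalizationParams] = None
) -> WindowedDataset:
    """Return a normalized copy of the dataset.

    Voltage: spike peaks standardized, then affinely mapped to [0, 1] from
    the fixed bounds (out-of-bounds samples are clipped and counted).
    Conductance channels: scaled by ``g_scale``.  Current channels: scaled
    to [-1, 1] by their training-split maximum absolute value (fitted here
    when not supplied).
    """
    if ds.normalized:
        raise ValueError("dataset is already normalized")
    current_cols = [i for i, n in enumerate(ds.channel_names) if n.startswith("i_")]
    if params is None:
        params = NormalizationParams()
    if current_cols and params.i_scale is None:
        train_rows = ds.index[ds.split_indices(TRAIN)]
        maxima = []
        for c in current_cols:
            m = 0.0
            for tid in np.unique(train_rows[:, 0]):
                ts = train_rows[train_rows[:, 0] == tid][:, 1]
                seg = ds.series[tid][ts.min() - ds.window : ts.max() + 1, c]
                m = max(m, float(np.abs(seg).max()))
            maxima.append(m if m > 0 else 1.0)
        params = replace(params, i_scale=maxima)
    n_clipped = 0
    new_series = []
    for mat in ds.series:
        out = mat.astype(np.float64).copy()
        v = out[:, 0]
        peaks = detect_spikes(v)
        v[peaks] = params.spike_peak_mV
        vn = params.normalize_v(v)
        n_clipped += int(np.sum((vn < 0) | (vn > 1)))
        out[:, 0] = np.clip(vn, 0.0, 1.0)
        for c, name in enumerate(ds.channel_names):
            if c == 0:
                continue
            if name.startswith("i_"):
                out[:, c] = out[:, c] / params.i_scale[current_cols.index(c)]
            else:
                out[:, c] = out[:, c] * params.g_scale
        new_series.append(out.astype(np.float32))
    if n_clipped:
        logger.warning("normalize: clipped %d out-of-bounds voltage samples", n_clipped)
    return WindowedDataset(
        series=new_series,
        channel_names=list(ds.channel_names),
        window=ds.window,
        target_channels=list(ds.target_channels),
        index=ds.index.copy(),
        split=ds.split.copy(),
        norm=params,
        normalized=True,
        n_clipped=n_clipped,
    )


@dataclass
class CurriculumBatches:
    """Staged training plan: resting -> subthreshold -> suprathreshold, with
    replay of earlier stages mixed into later-stage batches."""

    stages: Dict[str, WindowedDataset]
    mix_fraction: float = 0.3
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.stages:
            if name not in CURRICULUM_ORDER:
                raise ValueError(f"unknown curriculum stage: {name}")
        if not self.stages:
            raise ValueError("curriculum requires at least one stage corpus")
        for name, ds in self.stages.items():
            if len(ds) == 0:
                raise ValueError(f"curriculum stage '{name}' is empty")

    @property
    def stage_names(self) -> List[str]:
        return [n for n in CURRICULUM_ORDER if n in self.stages]

    def epoch(self, stage: str, epoch_seed: int = 0) -> Iterator[Tuple[np.ndarray, np.ndarray]]:
        """Yield (X, y) batches for one epoch of a stage.  Batches hold
        ``mix_fraction`` replay windows from all earlier stages."""
        rng = np.random.default_rng((self.seed, epoch_seed, self.stage_names.index(stage)))
        ds = self.stages[stage]
        own = rng.permutation(ds.split_indices(TRAIN))
        earlier = [
            self.stages[s] for s in self.stage_names[: self.stage_names.index(stage)]
        ]
        n_replay = int(round(self.mix_fraction * self.batch_size)) if earlier else 0
        n_own = self.batch_size - n_replay
        for start in range(0, len(own), n_own):
            chunk = own[start : start + n_own]
            X, y = ds.gather(chunk)
            if n_replay and earlier:
                k = rng.integers(len(earlier), size=n_replay)
                Xr, yr = [], []
                for j, src in enumerate(earlier):
                    take = int(np.sum(k == j))
                    if take:
                        pool = src.split_indices(TRAIN)
                        Xs, ys = src.gather(rng.choice(pool, size=take))
                        Xr.append(Xs)
                        yr.append(ys)
                X = np.concatenate([X] + Xr)
                y = np.concatenate([y] + yr)
            yield X, y
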
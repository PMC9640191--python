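"""Synaptic event trains: timestamped events with identity, polarity and weight."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXC = "exc"
INH = "inh"


@dataclass
class EventTrain:
    """A sorted train of synaptic events.

    Attributes
    ----------
    onset_ms : float array, event onset times (ms).
    synapse_id : int array, which synapse (point models: index into the
        synapse list; cable models: dendritic site index).
    weight_nS : float array, quantal peak conductance of each event.
    polarity : object array of ``"exc"`` / ``"inh"`` labels.
    """

    onset_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    synapse_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    weight_nS: np.ndarray = field(default_factory=lambda: np.empty(0))
    polarity: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.synapse_id = np.asarray(self.synapse_id, dtype=np.int64)
        self.weight_nS = np.asarray(self.weight_nS, dtype=float)
        self.polarity = np.asarray(self.polarity, dtype=object)
        n = len(self.onset_ms)
        if not (len(self.synapse_id) == len(self.weight_nS) == len(self.polarity) == n):
            raise ValueError("all event columns must have equal length")
        if np.any(self.weight_nS < 0):
            raise ValueError("event weights must be non-negative")
        order = np.argsort(self.onset_ms, kind="stable")
        self.onset_ms = self.onset_ms[order]
        self.synapse_id = self.synapse_id[order]
        self.weight_nS = self.weight_nS[order]
        self.polarity = self.polarity[order]

    def __len__(self) -> int:
        return len(self.onset_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": self.onset_ms,
                "synapse_id": self.synapse_id,
                "weight_nS": self.weight_nS,
                "polarity": self.polarity,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTrain":
        return cls(
            onset_ms=df["onset_ms"].to_numpy(dtype=float),
            synapse_id=df["synapse_id"].to_numpy(dtype=np.int64),
            weight_nS=df["weight_nS"].to_numpy(dtype=float),
            polarity=df["polarity"].to_numpy(dtype=object),
        )

    @classmethod
    def from_csv(cls, path) -> "EventTrain":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_lists(cls, events) -> "EventTrain":
        """Build from an iterable of (onset_ms, synapse_id, weight_nS, polarity)."""
        if not events:
            return cls()
        onset, sid, w, pol = zip(*events)
        return cls(np.array(onset), np.array(sid), np.array(w), np.array(pol, dtype=object))


def concat_trains(trains) -> EventTrain:
    trains = [t for t in trains if len(t)]
    if not trains:
        return EventTrain()
    return EventTrain(
        np.concatenate([t.onset_ms for t in trains]),
        np.concatenate([t.synapse_id for t in trains]),
        np.concatenate([t.weight_nS for t in trains]),
        np.concatenate([t.polarity for t in trains]),
    )
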
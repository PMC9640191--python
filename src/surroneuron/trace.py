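"""Uniformly sampled voltage (and optional ionic current) traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class VoltageTrace:
    """Membrane potential sampled at a fixed interval (default 1 kHz).

    Optional ionic current series (I_Na, I_K, in nA) and gating-variable
    series share the voltage time base.
    """

    v: np.ndarray
    dt_sample: float = 1.0
    i_na: Optional[np.ndarray] = None
    i_k: Optional[np.ndarray] = None
    gates: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")
        for name in ("i_na", "i_k"):
            series = getattr(self, name)
            if series is not None:
                series = np.asarray(series, dtype=float)
                if series.shape != self.v.shape:
                    raise ValueError(f"{name} length differs from v")
                setattr(self, name, series)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("voltage trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.v)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.v)) * self.dt_sample

    @property
    def duration_ms(self) -> float:
        return len(self.v) * self.dt_sample

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time_ms, "v_mV": self.v}
        if self.i_na is not None:
            data["i_na_nA"] = self.i_na
        if self.i_k is not None:
            data["i_k_nA"] = self.i_k
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VoltageTrace":
        df = pd.read_csv(path)
        dt = float(df["time_ms"].iloc[1] - df["time_ms"].iloc[0]) if len(df) > 1 else 1.0
        return cls(
            v=df["v_mV"].to_numpy(),
            dt_sample=dt,
            i_na=df["i_na_nA"].to_numpy() if "i_na_nA" in df else None,
            i_k=df["i_k_nA"].to_numpy() if "i_k_nA" in df else None,
        )
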
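"""Tsodyks-Markram short-term synaptic dynamics.

Per contact: utilization u (facilitation, recovering to 0 with time constant
F) and resources R (depression, recovering to 1 with time constant D).
Between spikes u and R relax exponentially; on a presynaptic spike u is
incremented by U(1-u), the released fraction is u*R, and R is depleted by
that amount.  The reference constants are U = 0.38, D = 365.6 ms,
F = 25.71 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TMParams:
    U: float = 0.38
    D_ms: float = 365.6
    F_ms: float = 25.71

    def __post_init__(self):
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must lie in (0, 1]")
        if self.D_ms <= 0 or self.F_ms <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class TMState:
    """Vectorized state for any number of contacts."""

    u: np.ndarray
    R: np.ndarray

    @classmethod
    def rested(cls, n: int) -> "TMState":
        return cls(u=np.zeros(n), R=np.ones(n))


def tm_update(
    state: TMState, dt_ms: float, presyn_spike, params: TMParams = TMParams()
) -> np.ndarray:
    """Advance the state by dt (exact exponential relaxation), then apply
    spike updates where ``presyn_spike`` is set; returns the release
    fraction per contact (zero where no spike occurred)."""
    state.u *= np.exp(-dt_ms / params.F_ms)
    state.R = 1.0 - (1.0 - state.R) * np.exp(-dt_ms / params.D_ms)
    spikes = np.asarray(presyn_spike, dtype=bool)
    release = np.zeros_like(state.u)
    if spikes.any():
        u_new = state.u[spikes] + params.U * (1.0 - state.u[spikes])
        rel = u_new * state.R[spikes]
        state.u[spikes] = u_new
        state.R[spikes] = state.R[spikes] - rel
        release[spikes] = rel
    return release
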
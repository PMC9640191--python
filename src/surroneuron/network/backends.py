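"""Cell backends for the network engine.

A backend advances a whole population one 1-ms sample per call, given the
excitatory and inhibitory conductance (nS) arriving at each cell during
that sample, and reports the new somatic voltage and spike flags.  All
cells share one backend instance, so the engine performs a single batched
forward pass per step regardless of population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from surroneuron import izhikevich as izh


class CellBackend:
    n_cells: int

    def advance(self, exc_nS: np.ndarray, inh_nS: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class IzhikevichBackend(CellBackend):
    """Population of identical Izhikevich cells with exponential synaptic
    current filters (tau_e / tau_i) converting delivered conductance into
    drive: I = k_e * s_e - k_i * s_i."""

    def __init__(
        self,
        n_cells: int,
        params: Optional[izh.IzhikevichParams] = None,
        k_e: float = 0.4,
        k_i: float = 0.1,
        tau_e_ms: float = 2.0,
        tau_i_ms: float = 1.0,
    ):
        self.n_cells = n_cells
        self.params = params or izh.FIRING_PATTERNS["fast_spiking"]
        self.k_e = k_e
        self.k_i = k_i
        self.decay_e = np.exp(-1.0 / tau_e_ms)
        self.decay_i = np.exp(-1.0 / tau_i_ms)
        vr, ur = self.params.rest()
        self.v = np.full(n_cells, vr)
        self.u = np.full(n_cells, ur)
        self.s_e = np.zeros(n_cells)
        self.s_i = np.zeros(n_cells)

    def advance(self, exc_nS, inh_nS):
        self.s_e = self.s_e * self.decay_e + exc_nS
        self.s_i = self.s_i * self.decay_i + inh_nS
        drive = self.k_e * self.s_e - self.k_i * self.s_i
        self.v, self.u, spiked = izh.step_many(self.v, self.u, drive, self.params)
        v_out = np.where(spiked, izh.SPIKE_CUTOFF, self.v)
        return v_out, spiked


class SurrogateBackend(CellBackend):
    """Population of cells simulated by one trained forecasting model.

    Each cell holds a rolling normalized input window; delivered
    conductances are written onto the excitatory/inhibitory channels and the
    model's own voltage predictions are fed back.  Spikes are detected as
    upward crossings of the 0-mV level of the denormalized voltage.
    """

    def __init__(self, n_cells: int, model, window_init: Optional[np.ndarray] = None):
        if model.norm is None:
            raise ValueError("surrogate backend needs a model with normalization params")
        self.n_cells = n_cells
        self.model = model
        self.window = model.spec.window
        C = model.spec.input_channels
        names = model.channel_names or ["v", "exc", "inh"]
        self.exc_col = names.index("exc")
        self.inh_col = names.index("inh")
        v0 = model.norm.normalize_v(-70.0)
        self.buf = np.zeros((n_cells, self.window, C))
        self.buf[:, :, 0] = v0
        if window_init is not None:
            self.buf[:] = window_init
        self._prev_v = np.full(n_cells, -70.0)

    def advance(self, exc_nS, inh_nS):
        norm = self.model.norm
        new_col = np.zeros((self.n_cells, 1, self.buf.shape[2]))
        new_col[:, 0, self.exc_col] = exc_nS * norm.g_scale
        new_col[:, 0, self.inh_col] = inh_nS * norm.g_scale
        window = np.concatenate([self.buf[:, 1:, :], new_col], axis=1)
        # predict the voltage for the incoming sample from the shifted window
        y = self.model.net.forward(window, training=False)
        window[:, -1, 0] = y[:, 0]
        self.buf = window
        v = norm.denormalize_v(y[:, 0])
        spiked = (self._prev_v < 0.0) & (v >= 0.0)
        self._prev_v = v
        return v, spiked


class ScriptedBackend(CellBackend):
    """Deterministic backend replaying a prescribed spike raster; used for
    engine contract tests.  Records every input it receives."""

    def __init__(self, spike_raster: np.ndarray, v_rest: float = -65.0):
        self.raster = np.asarray(spike_raster, dtype=bool)  # (n_cells, T)
        self.n_cells = self.raster.shape[0]
        self.t = 0
        self.v_rest = v_rest
        self.received_exc: List[np.ndarray] = []
        self.received_inh: List[np.ndarray] = []

    def advance(self, exc_nS, inh_nS):
        self.received_exc.append(np.array(exc_nS))
        self.received_inh.append(np.array(inh_nS))
        spiked = (
            self.raster[:, self.t]
            if self.t < self.raster.shape[1]
            else np.zeros(self.n_cells, dtype=bool)
        )
        self.t += 1
        v = np.where(spiked, 30.0, self.v_rest)
        return v, spiked
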
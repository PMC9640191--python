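"""Batched recurrent-network simulation.

Every step (1 ms): deliveries scheduled for this sample plus background
drive and the stimulus are handed to the shared cell backend; spikes
detected at this sample update each presynaptic cell's short-term
(Tsodyks-Markram) state and schedule conductance onto the excitatory
channels of connected postsynaptic cells one synaptic delay later.  The
delivered conductance per connection is
g_conn * multiplier * n_contacts * excitation_scale * release.

The Rett-syndrome parameter sweep scans recurrent excitation scale and
connection probability (optionally background-inhibition scale), scoring
each run by its pre-stimulus population spike count (instability) and the
number of cells firing within 10 ms of the stimulus (immediate response).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from surroneuron import stimgen
from surroneuron.network.backends import CellBackend
from surroneuron.network.connectivity import ConnectivityMatrix, build_connectivity
from surroneuron.network.tm import TMParams, TMState, tm_update


@dataclass
class NetworkConfig:
    n_cells: int = 150
    p_uni: float = 0.10
    g_conn_nS: float = 1.0
    n_contacts: int = 5
    delay_ms: int = 1
    stimulus_time_ms: float = 100.0
    stimulus_nS: float = 50.0
    duration_ms: float = 250.0
    excitation_scale: float = 1.0  # scales recurrent quantal size
    inhibition_scale: float = 1.0  # scales background inhibitory quantal size
    background_rate_hz: float = 1500.0  # total background events per cell
    background_exc_nS: float = 2.5
    background_inh_nS: float = 8.0
    settle_discard_ms: float = 10.0
    stability_threshold: int = 5  # pre-stimulus APs below which a run counts as stable
    immediate_window_ms: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.delay_ms < 1:
            raise ValueError("synaptic delay must be at least one sample")
        if self.duration_ms <= self.stimulus_time_ms:
            raise ValueError("duration must exceed the stimulus time")


@dataclass
class NetworkResult:
    raster: List[Tuple[int, int]]  # (cell, spike-time ms)
    v: Optional[np.ndarray]  # (n_cells, T) when recorded
    config: NetworkConfig
    delivered_total_nS: float
    expected_delivered_nS: float

    def spike_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raster, columns=["cell", "spike_time_ms"])

    def pre_stimulus_count(self) -> int:
        return sum(
            1
            for _, t in self.raster
            if self.config.settle_discard_ms <= t < self.config.stimulus_time_ms
        )

    def immediate_response(self) -> int:
        t0 = self.config.stimulus_time_ms
        t1 = t0 + self.config.immediate_window_ms
        return len({c for c, t in self.raster if t0 <= t < t1})


def _background_inputs(config: NetworkConfig, rng: np.random.Generator, n_steps: int):
    """Per-cell background event channels (exc, inh) in nS per sample."""
    exc = np.zeros((config.n_cells, n_steps))
    inh = np.zeros((config.n_cells, n_steps))
    n_events = int(round(config.background_rate_hz * config.duration_ms / 1000.0))
    for c in range(config.n_cells):
        train = stimgen.random_train(
            config.duration_ms,
            n_events,
            seed=int(rng.integers(2**31)),
            exc_weight_nS=config.background_exc_nS,
            inh_weight_nS=config.background_inh_nS * config.inhibition_scale,
        )
        for onset, w, pol in zip(train.onset_ms, train.weight_nS, train.polarity):
            s = int(onset)
            if s < n_steps:
                (exc if pol == "exc" else inh)[c, s] += w
    return exc, inh


def run_network(
    config: NetworkConfig,
    backend: CellBackend,
    connectivity: Optional[ConnectivityMatrix] = None,
    tm_params: TMParams = TMParams(),
    record_v: bool = False,
    background: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> NetworkResult:
    if backend.n_cells != config.n_cells:
        raise ValueError("backend population size differs from config")
    rng = np.random.default_rng(config.seed)
    if connectivity is None:
        connectivity = build_connectivity(
            config.n_cells, config.p_uni, seed=int(rng.integers(2**31))
        )
    n = config.n_cells
    n_steps = int(round(config.duration_ms))
    if background is None:
        background = _background_inputs(config, rng, n_steps)
    bg_exc, bg_inh = background

    weight = connectivity.x * connectivity.multiplier  # (pre, post)
    tm_state = TMState.rested(n)  # one state per presynaptic cell
    pending = np.zeros((config.delay_ms + 1, n))  # ring buffer of deliveries
    raster: List[Tuple[int, int]] = []
    v_rec = np.empty((n, n_steps)) if record_v else None
    delivered_total = 0.0
    expected_total = 0.0
    stim_step = int(round(config.stimulus_time_ms))
    quantal = config.g_conn_nS * config.n_contacts * config.excitation_scale

    for t in range(n_steps):
        slot = t % (config.delay_ms + 1)
        exc_in = bg_exc[:, t] + pending[slot]
        delivered_total += float(pending[slot].sum())
        pending[slot] = 0.0
        if t == stim_step:
            exc_in = exc_in + config.stimulus_nS
        v, spiked = backend.advance(exc_in, bg_inh[:, t])
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise RuntimeError(f"backend produced a non-finite voltage (cell {bad}, step {t})")
        if record_v:
            v_rec[:, t] = v
        release = tm_update(tm_state, 1.0, spiked, tm_params)
        if spiked.any():
            for c in np.flatnonzero(spiked):
                raster.append((int(c), t))
            delivery = quantal * (weight.T @ release)  # (post,)
            target = (t + config.delay_ms) % (config.delay_ms + 1)
            pending[target] += delivery
            expected_total += float(delivery.sum())
    return NetworkResult(
        raster=raster,
        v=v_rec,
        config=config,
        delivered_total_nS=delivered_total,
        expected_delivered_nS=expected_total,
    )


@dataclass
class SweepResult:
    excitation_scale: float
    p_uni: float
    inhibition_scale: float
    repeat: int
    instability: int
    immediate_response: int
    stable: bool


def run_rett_sweep(
    excitation_scales: Sequence[float],
    p_uni_values: Sequence[float],
    backend_factory: Callable[[NetworkConfig], CellBackend],
    inhibition_scales: Sequence[float] = (1.0,),
    repeats: int = 3,
    base_config: Optional[NetworkConfig] = None,
    seed: int = 0,
) -> List[SweepResult]:
    """Parameter-space map over recurrent excitation and connectivity.

    For each grid cell and repeat a fresh connectivity matrix, background
    realization and backend are drawn; the run is scored by instability
    (pre-stimulus population APs, first ``settle_discard_ms`` discarded) and
    immediate response (cells firing within 10 ms of the stimulus).
    """
    if not len(excitation_scales) or not len(p_uni_values):
        raise ValueError("sweep grid must be nonempty")
    base = base_config or NetworkConfig()
    root = np.random.default_rng(seed)
    results = []
    for inh_scale in inhibition_scales:
        for exc_scale in excitation_scales:
            for p_uni in p_uni_values:
                for rep in range(repeats):
                    from dataclasses import replace

                    config = replace(
                        base,
                        excitation_scale=float(exc_scale),
                        inhibition_scale=float(inh_scale),
                        p_uni=float(p_uni),
                        seed=int(root.integers(2**31)),
                    )
                    backend = backend_factory(config)
                    res = run_network(config, backend)
                    inst = res.pre_stimulus_count()
                    results.append(
                        SweepResult(
                            excitation_scale=float(exc_scale),
                            p_uni=float(p_uni),
                            inhibition_scale=float(inh_scale),
                            repeat=rep,
                            instability=inst,
                            immediate_response=res.immediate_response(),
                            stable=inst < config.stability_threshold,
                        )
                    )
    return results


def sweep_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
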
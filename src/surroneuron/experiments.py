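"""End-to-end experiment pipelines.

These functions tie the simulator, dataset, training and evaluation layers
into the standard characterization experiments; they are used by the test
suite, the reproduction script and the examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from surroneuron import stimgen
from surroneuron.architectures import SurrogateModel, build
from surroneuron.biophys.model import (
    CompartmentModelSpec,
    active_point_model,
    excitatory_synapse,
    fast_spiking_model,
    inhibitory_synapse,
    passive_point_model,
)
from surroneuron.biophys.point import simulate_point_neuron, steady_state_init
from surroneuron.closed_loop import autoregressive_many
from surroneuron.data import make_windows, normalize
from surroneuron.evaluation import IVSummary, explained_variance, iv_summary
from surroneuron.events import EventTrain
from surroneuron import izhikevich as izh
from surroneuron.spikes import spike_times_ms
from surroneuron.trace import VoltageTrace
from surroneuron.training import TrainingConfig, train


# -- quantal conductance sweep ------------------------------------------------


@dataclass
class SweepResultSummary:
    summary: IVSummary
    conductances_nS: np.ndarray
    traces: List[VoltageTrace]
    first_spiking_nS: Optional[float]


def quantal_sweep_experiment(
    model: Optional[CompartmentModelSpec] = None,
    g_min_nS: float = 0.1,
    g_max_nS: float = 3.5,
    step_nS: float = 0.1,
    duration_ms: float = 150.0,
    onset_ms: float = 20.0,
    extend_until_spike: bool = True,
    max_extension_nS: float = 2.0,
) -> SweepResultSummary:
    """Single excitatory alpha-synapse events of increasing quantal size on
    the active point neuron; summarizes the subthreshold I/V relation and
    the AP threshold.

    If no trial in the requested grid spikes, the grid is extended upward in
    the same increments until one does (the threshold estimate needs one
    suprathreshold trial to bracket the maximal subthreshold depolarization).
    """
    if model is None:
        model = active_point_model()
    init = steady_state_init(model)
    syn = [excitatory_synapse()]
    gs = list(g_min_nS + step_nS * np.arange(int(round((g_max_nS - g_min_nS) / step_nS)) + 1))
    traces = []
    for g in gs:
        ev = EventTrain.from_lists([(onset_ms, 0, float(g), "exc")])
        traces.append(simulate_point_neuron(model, syn, ev, duration_ms, init=init))
    first_spiking = None
    spiking = [float(np.max(t.v)) >= 0.0 for t in traces]
    if any(spiking):
        first_spiking = gs[int(np.argmax(spiking))]
    elif extend_until_spike:
        g = gs[-1]
        while g < g_max_nS + max_extension_nS:
            g += step_nS
            ev = EventTrain.from_lists([(onset_ms, 0, float(g), "exc")])
            tr = simulate_point_neuron(model, syn, ev, duration_ms, init=init)
            gs.append(g)
            traces.append(tr)
            if float(np.max(tr.v)) >= 0.0:
                first_spiking = g
                break
    summary = iv_summary(gs, traces)
    return SweepResultSummary(
        summary=summary,
        conductances_nS=np.asarray(gs),
        traces=traces,
        first_spiking_nS=first_spiking,
    )


# -- Izhikevich layer constrained on a fast-spiking teacher -------------------


def _alpha_current_waveform(
    duration_ms: int, n_events: int, amp_range_nA: Tuple[float, float],
    tau_ms: float, rng: np.random.Generator,
) -> np.ndarray:
    """Sum of alpha-shaped current transients at random onsets (1 kHz)."""
    t = np.arange(0, int(10 * tau_ms))
    kernel = (t / tau_ms) * np.exp(1.0 - t / tau_ms)
    impulses = np.zeros(duration_ms)
    onsets = rng.integers(0, duration_ms - 1, size=n_events)
    amps = rng.uniform(*amp_range_nA, size=n_events)
    np.add.at(impulses, onsets, amps)
    return np.convolve(impulses, kernel)[:duration_ms]


@dataclass
class IzhikevichFitReport:
    params: izh.IzhikevichParams
    fi_amps_nA: np.ndarray
    teacher_rates_hz: np.ndarray
    fitted_rates_hz: np.ndarray
    fi_pearson_r: float
    subthreshold_ev: float  # mean over validation waveforms
    subthreshold_evs: np.ndarray
    objective: float


def izhikevich_fit_experiment(
    seed: int = 0,
    n_starts: int = 20,
    fi_amps_nA: Optional[np.ndarray] = None,
    step_duration_ms: float = 2000.0,
    sub_duration_ms: int = 2000,
    n_validation: int = 5,
    model: Optional[CompartmentModelSpec] = None,
) -> IzhikevichFitReport:
    """Constrain the five-parameter spiking layer on a fast-spiking
    conductance-based teacher.

    Ground truth: an f-I table from constant current steps plus subthreshold
    voltage responses to fluctuating current waveforms shared by teacher and
    layer.  Reports the f-I Pearson correlation and the explained variance of
    continuous subthreshold prediction on held-out waveforms.
    """
    if model is None:
        model = fast_spiking_model()
    init = steady_state_init(model)
    if fi_amps_nA is None:
        # rising branch of the teacher's f-I curve (below depolarization block)
        fi_amps_nA = np.arange(0.0, 0.201, 0.02)
    discard_ms = 200.0
    rates = []
    for a in fi_amps_nA:
        tr = simulate_point_neuron(
            model, [], EventTrain(), step_duration_ms + discard_ms + 100.0, init=init,
            i_inj=(float(a), 50.0, 50.0 + discard_ms + step_duration_ms),
        )
        spk = spike_times_ms(tr.v)
        spk = spk[spk >= 50.0 + discard_ms]  # steady-state rate
        rates.append(len(spk) / (step_duration_ms / 1000.0))
    rates = np.asarray(rates)

    # teacher passive properties for the system-identification initial guess
    probe = simulate_point_neuron(
        model, [], EventTrain(), 300.0, init=init, i_inj=(-0.01, 50.0, 300.0)
    )
    delta = probe.v - init.v
    r_in = abs(float(delta[-1])) / 0.01
    target = 0.632 * delta[-1]
    tau = max(float(np.argmax(np.abs(delta[50:]) >= abs(target))), 0.5)

    rng = np.random.default_rng(seed)

    def subthreshold_pair(wave_rng):
        """Small-signal synaptic current waveform and the teacher's
        subthreshold response, aligned so the layer's output after
        integrating drive sample t is compared with teacher sample t+1."""
        amp_hi = 0.003
        while True:
            drive = _alpha_current_waveform(
                sub_duration_ms, n_events=int(sub_duration_ms * 0.05),
                amp_range_nA=(0.001, amp_hi), tau_ms=10.0, rng=wave_rng,
            )
            tr = simulate_point_neuron(
                model, [], EventTrain(), float(sub_duration_ms), init=init, i_inj=drive
            )
            if len(spike_times_ms(tr.v)) == 0:
                return drive[:-1], tr.v[1:]
            amp_hi *= 0.7  # keep the corpus subthreshold by construction

    # fit on several independent waveforms, joined by relaxation gaps so the
    # layer's state settles between them
    gap = np.zeros(300)
    drives, vs = [], []
    for _ in range(3):
        d, v = subthreshold_pair(np.random.default_rng(rng.integers(2**31)))
        drives += [d, gap]
        vs += [v, np.full(300, init.v)]
    fit_drive = np.concatenate(drives[:-1])
    fit_v = np.concatenate(vs[:-1])

    init_params = izh.init_from_passive_properties(init.v, r_in, tau)
    result = izh.fit(
        fi_table=(fi_amps_nA, rates),
        subthreshold=(fit_drive, fit_v),
        init=init_params,
        n_starts=n_starts,
        seed=int(rng.integers(2**31)),
    )
    fitted_rates = izh.fi_curve(result.params, fi_amps_nA, duration_ms=step_duration_ms, discard_ms=discard_ms)
    r = float(np.corrcoef(fitted_rates, rates)[0, 1])
    evs = []
    for _ in range(n_validation):
        drive, v_true = subthreshold_pair(np.random.default_rng(rng.integers(2**31)))
        v_pred, _ = izh.run(result.params, drive)
        evs.append(explained_variance(v_pred, v_true))
    evs = np.asarray(evs)
    return IzhikevichFitReport(
        params=result.params,
        fi_amps_nA=np.asarray(fi_amps_nA),
        teacher_rates_hz=rates,
        fitted_rates_hz=fitted_rates,
        fi_pearson_r=r,
        subthreshold_ev=float(evs.mean()),
        subthreshold_evs=evs,
        objective=result.objective,
    )


# -- linear surrogate on the passive point neuron -----------------------------


@dataclass
class PassiveForecastReport:
    model: SurrogateModel
    evs: np.ndarray  # per-run explained variance (fractions)
    mean_ev_percent: float
    history_rows: int


def passive_corpus(
    n_traces: int, trace_ms: float, events_per_trace: int, seed: int,
    model: Optional[CompartmentModelSpec] = None,
):
    """Passive point-neuron corpus under 8:3 random trains (1 kHz traces)."""
    if model is None:
        model = passive_point_model()
    init = steady_state_init(model)
    syn = [excitatory_synapse(), inhibitory_synapse()]
    pairs = []
    for k in range(n_traces):
        train = stimgen.random_train(trace_ms, events_per_trace, seed=seed * 10007 + k)
        tr = simulate_point_neuron(model, syn, train, trace_ms, init=init)
        pairs.append((tr, train))
    return pairs, model, init, syn


def linear_passive_experiment(
    seed: int = 0,
    n_traces: int = 8,
    trace_ms: float = 10000.0,
    events_per_trace: int = 500,
    n_runs: int = 50,
    horizon_ms: float = 500.0,
    max_epochs: int = 150,
    patience: int = 20,
) -> PassiveForecastReport:
    """Train the linear architecture on a passive corpus and evaluate fifty
    500-ms continuous self-reliant predictions on held-out event trains."""
    pairs, model, init, syn = passive_corpus(n_traces, trace_ms, events_per_trace, seed)
    ds = normalize(make_windows(pairs))
    surrogate = build("linear", input_channels=3, seed=seed)
    config = TrainingConfig(
        optimizer="adam_nesterov", loss="mse", patience=patience,
        max_epochs=max_epochs, batch_size=256, seed=seed,
    )
    surrogate, history = train(surrogate, ds, config)

    window = surrogate.spec.window
    rate_ms = events_per_trace / trace_ms
    runs = []
    truths = []
    for k in range(n_runs):
        total = window + horizon_ms
        train_k = stimgen.random_train(
            total, int(round(rate_ms * total)), seed=seed * 20011 + 7919 + k
        )
        tr = simulate_point_neuron(model, syn, train_k, total, init=init)
        init_tr = VoltageTrace(v=tr.v[:window], dt_sample=1.0)
        runs.append((init_tr, train_k))
        truths.append(tr.v[window:])
    preds = autoregressive_many(surrogate, runs, horizon_ms)
    evs = np.array([explained_variance(p.v, t) for p, t in zip(preds, truths)])
    return PassiveForecastReport(
        model=surrogate,
        evs=evs,
        mean_ev_percent=float(evs.mean() * 100.0),
        history_rows=len(history),
    )
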
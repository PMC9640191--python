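"""Quantitative metrics: explained variance, spike-train matching,
firing-rate model comparison, and quantal-sweep (I/V) summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from surroneuron.spikes import detect_spikes, spike_times_ms
from surroneuron.trace import VoltageTrace


def explained_variance(pred, truth) -> float:
    """1 - MSE(pred, truth) / var(truth); 1 is perfect, 0 matches predicting
    the mean, negative values are possible."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    var = float(np.var(truth))
    if var == 0:
        raise ValueError("truth signal is constant; explained variance undefined")
    mse = float(np.mean((pred - truth) ** 2))
    return 1.0 - mse / var


@dataclass
class SpikeMatchReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    shifts_ms: np.ndarray
    window_ms: float
    degenerate: bool = False  # a rate was undefined and reported as its convention

    @property
    def mean_shift_ms(self) -> float:
        return float(np.mean(self.shifts_ms)) if len(self.shifts_ms) else float("nan")

    @property
    def sd_shift_ms(self) -> float:
        return float(np.std(self.shifts_ms)) if len(self.shifts_ms) else float("nan")


def match_spike_trains(
    pred_times_ms: np.ndarray, true_times_ms: np.ndarray, window_ms: float = 10.0
) -> SpikeMatchReport:
    """Greedy one-to-one matching of predicted to true spikes.

    Candidate pairs within +/- window/2 are matched in ascending |shift|
    order, so each spike is used at most once.  Precision with no predicted
    spikes is reported as 0, recall with no true spikes as 1 (both flagged).
    """
    pred = np.asarray(pred_times_ms, dtype=float)
    true = np.asarray(true_times_ms, dtype=float)
    half = window_ms / 2.0
    pairs = []
    for i, tp_ in enumerate(pred):
        for j, tt in enumerate(true):
            if abs(tp_ - tt) <= half:
                pairs.append((abs(tp_ - tt), i, j))
    pairs.sort()
    used_p: set = set()
    used_t: set = set()
    shifts = []
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        shifts.append(pred[i] - true[j])
    tp = len(shifts)
    fp = len(pred) - tp
    fn = len(true) - tp
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 1.0, True
    return SpikeMatchReport(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
        shifts_ms=np.asarray(shifts), window_ms=window_ms, degenerate=degenerate,
    )


def spike_match(
    pred: Union[VoltageTrace, np.ndarray],
    true: Union[VoltageTrace, np.ndarray],
    window_ms: float = 10.0,
) -> SpikeMatchReport:
    """Spike matching on traces (spikes detected as 0-mV upward crossings)
    or directly on spike-time arrays."""
    def times(x):
        if isinstance(x, VoltageTrace):
            return spike_times_ms(x.v, x.dt_sample)
        return np.asarray(x, dtype=float)

    return match_spike_trains(times(pred), times(true), window_ms)


# -- firing-rate model comparison --------------------------------------------


def logistic4(x, a1, a2, x0, dx):
    return (a1 - a2) / (1.0 + np.exp(np.clip((x - x0) / dx, -500, 500))) + a2


@dataclass
class FiringModelFit:
    linear: Tuple[float, float]  # (a, b) in y = a + b x
    logistic: Optional[Tuple[float, float, float, float]]  # (A1, A2, x0, dx)
    aic_linear: float
    aic_logistic: float
    winner: str
    residuals_linear: np.ndarray
    residuals_logistic: Optional[np.ndarray]
    fallback: bool = False


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_firing_models(input_rate: np.ndarray, output_rate: np.ndarray) -> FiringModelFit:
    """Fit the linear (subtractive/divisive inhibition) and 4-parameter
    logistic (divisive normalization) descriptions of the rate transfer and
    compare by AIC (Gaussian least-squares form n*ln(RSS/n) + 2k)."""
    x = np.asarray(input_rate, dtype=float)
    y = np.asarray(output_rate, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points to compare rate models")
    b, a = np.polyfit(x, y, 1)
    res_lin = y - (a + b * x)
    aic_lin = _aic(float(np.sum(res_lin**2)), len(x), 2)

    logistic_params = None
    res_log = None
    aic_log = np.inf
    fallback = False
    try:
        span = y.max() - y.min()
        p0 = (y.max(), y.min(), float(np.median(x)), -(x.max() - x.min()) / 4 or -1.0)
        popt, _ = curve_fit(logistic4, x, y, p0=p0, maxfev=20000)
        res_log = y - logistic4(x, *popt)
        aic_log = _aic(float(np.sum(res_log**2)), len(x), 4)
        logistic_params = tuple(float(v) for v in popt)
    except Exception:
        fallback = True
    winner = "linear" if aic_lin <= aic_log else "logistic"
    return FiringModelFit(
        linear=(float(a), float(b)),
        logistic=logistic_params,
        aic_linear=float(aic_lin),
        aic_logistic=float(aic_log),
        winner=winner,
        residuals_linear=res_lin,
        residuals_logistic=res_log,
        fallback=fallback,
    )


# -- quantal sweep summary ----------------------------------------------------


@dataclass
class IVSummary:
    slope_mV_per_nS: float
    intercept_mV: float
    pearson_r: float  # over all subthreshold trials
    ap_threshold_mV: Optional[float]  # maximal subthreshold depolarization
    n_subthreshold: int
    linear_mask: np.ndarray = field(repr=False, default=None)


def iv_summary(
    conductances_nS: Sequence[float],
    traces: Sequence[VoltageTrace],
    linearity_tol: float = 0.05,
    n_anchor: int = 5,
) -> IVSummary:
    """Summary of a quantal conductance sweep.

    Peak response amplitude (relative to the pre-event baseline) is measured
    per trial; non-spiking trials form the subthreshold set.  The
    ``subthreshold linear`` regime is the initial run of trials whose
    amplitude stays within ``linearity_tol`` of the low-conductance linear
    prediction (anchored on the first ``n_anchor`` subthreshold trials);
    slope and intercept come from an OLS fit over that regime.  The AP
    threshold is estimated as the maximal subthreshold membrane potential:
    the peak voltage of the largest non-spiking trial preceding the first
    spiking one (None if nothing spikes).
    """
    g = np.asarray(conductances_nS, dtype=float)
    if len(g) != len(traces):
        raise ValueError("conductance and trace counts differ")
    peaks = np.array([float(np.max(t.v)) for t in traces])
    base = np.array([float(t.v[0]) for t in traces])
    amps = peaks - base
    spiking = peaks >= 0.0
    sub = ~spiking
    if sub.sum() < max(n_anchor, 3):
        raise ValueError("too few subthreshold trials for an I/V fit")
    gs, as_ = g[sub], amps[sub]
    order = np.argsort(gs)
    gs, as_ = gs[order], as_[order]
    b0, a0 = np.polyfit(gs[:n_anchor], as_[:n_anchor], 1)
    predicted = a0 + b0 * gs
    within = np.abs(as_ - predicted) <= linearity_tol * np.abs(predicted)
    # initial contiguous run (linear regime extends from the smallest quanta)
    n_lin = int(np.argmin(within)) if not within.all() else len(within)
    n_lin = max(n_lin, n_anchor)
    slope, intercept = np.polyfit(gs[:n_lin], as_[:n_lin], 1)
    r = float(np.corrcoef(gs, as_)[0, 1])
    threshold = None
    if spiking.any():
        first_spk = int(np.flatnonzero(spiking)[0])
        below = np.flatnonzero(sub[:first_spk])
        if len(below):
            threshold = float(peaks[below[-1]])
    mask = np.zeros(len(g), dtype=bool)
    sub_idx = np.flatnonzero(sub)[order]
    mask[sub_idx[:n_lin]] = True
    return IVSummary(
        slope_mV_per_nS=float(slope),
        intercept_mV=float(intercept),
        pearson_r=r,
        ap_threshold_mV=threshold,
        n_subthreshold=int(sub.sum()),
        linear_mask=mask,
    )
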
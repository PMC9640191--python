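"""Single-compartment simulator.

Integration uses exponential Euler for the channel gates and synaptic states
and an implicit (backward) Euler step for the voltage, at an internal step of
25 us.  Output is decimated to 1 kHz by keeping the sample at each integer
millisecond; a fine-resolution trace can be requested for threshold
measurements.  Alpha-synapse conductances are propagated by their exact
two-state exponential recursion, so the transient g(t) = w*(t/tau)*exp(1-t/tau)
is reproduced to machine precision at the grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

from surroneuron.biophys.model import CompartmentModelSpec, SynapseSpec
from surroneuron.biophys.hh import steady_state_gates, resting_potential
from surroneuron.events import EventTrain
from surroneuron.trace import VoltageTrace

INTERNAL_DT_MS = 0.025
E_CONST = math.e


@dataclass
class InitialState:
    v: float
    m: float
    h: float
    n: float
    drift_mV: float = 0.0


@njit(cache=True)
def _rates(v, kdr_shift):
    # m
    x = -(v + 40.0)
    am = 0.1 * (10.0 * (1.0 - x / 20.0) if abs(x / 10.0) < 1e-6 else x / (math.expm1(x / 10.0)))
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    # h
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    # n (shifted)
    vs = v - kdr_shift
    xn = -(vs + 55.0)
    an = 0.01 * (10.0 * (1.0 - xn / 20.0) if abs(xn / 10.0) < 1e-6 else xn / (math.expm1(xn / 10.0)))
    bn = 0.125 * math.exp(-(vs + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _integrate(
    v0,
    m0,
    h0,
    n0,
    dt,
    n_steps,
    c_nF,
    g_leak,
    e_leak,
    gna,
    ena,
    gk,
    ek,
    kdr_shift,
    active,
    syn_tau,
    syn_erev,
    syn_gated,
    bolt_a1,
    bolt_a2,
    bolt_x0,
    bolt_dx,
    ev_step,
    ev_syn,
    ev_w_uS,
    i_inj,
    record_every,
    record_currents,
):
    n_syn = syn_tau.shape[0]
    g_state = np.zeros(n_syn)
    y_state = np.zeros(n_syn)
    decay = np.empty(n_syn)
    for s in range(n_syn):
        decay[s] = math.exp(-dt / syn_tau[s])

    n_rec = n_steps // record_every
    v_rec = np.empty(n_rec)
    ina_rec = np.empty(n_rec if record_currents else 0)
    ik_rec = np.empty(n_rec if record_currents else 0)

    v = v0
    m = m0
    h = h0
    n = n0
    ev_i = 0
    n_ev = ev_step.shape[0]
    has_inj = i_inj.shape[0] > 0
    rec_i = 0

    for step in range(n_steps):
        if step % record_every == 0 and rec_i < n_rec:
            v_rec[rec_i] = v
            if record_currents:
                ina_rec[rec_i] = gna * m * m * m * h * (v - ena)  # uS * mV = nA
                ik_rec[rec_i] = gk * n * n * n * n * (v - ek)
            rec_i += 1

        # deliver events scheduled at this step
        while ev_i < n_ev and ev_step[ev_i] == step:
            s = ev_syn[ev_i]
            y_state[s] += ev_w_uS[ev_i] * E_CONST / syn_tau[s]
            ev_i += 1

        # advance synaptic states (exact for the alpha system)
        for s in range(n_syn):
            g_state[s] = (g_state[s] + dt * y_state[s]) * decay[s]
            y_state[s] *= decay[s]

        # advance gates (exponential Euler at current voltage)
        if active:
            am, bm, ah, bh, an, bn = _rates(v, kdr_shift)
            sm = am + bm
            sh = ah + bh
            sn = an + bn
            m = am / sm + (m - am / sm) * math.exp(-dt * sm)
            h = ah / sh + (h - ah / sh) * math.exp(-dt * sh)
            n = an / sn + (n - an / sn) * math.exp(-dt * sn)

        # implicit voltage update
        g_tot = g_leak
        ge_sum = g_leak * e_leak
        if active:
            gna_t = gna * m * m * m * h
            gk_t = gk * n * n * n * n
            g_tot += gna_t + gk_t
            ge_sum += gna_t * ena + gk_t * ek
        for s in range(n_syn):
            gs = g_state[s]
            if syn_gated[s] == 1:
                scale = bolt_a2[s] + (bolt_a1[s] - bolt_a2[s]) / (
                    1.0 + math.exp((bolt_x0[s] - v) / bolt_dx[s])
                )
                if scale < 0.0:
                    scale = 0.0
                gs *= scale
            g_tot += gs
            ge_sum += gs * syn_erev[s]
        inj = i_inj[step] if has_inj else 0.0
        k = dt / c_nF
        v = (v + k * (ge_sum + inj)) / (1.0 + k * g_tot)
        if not math.isfinite(v):
            return v_rec[:rec_i], ina_rec[:rec_i], ik_rec[:rec_i], v, m, h, n, step
    return v_rec, ina_rec, ik_rec, v, m, h, n, -1


def _prepare_synapse_arrays(synapses: Sequence[SynapseSpec]):
    n = len(synapses)
    tau = np.array([s.tau_ms for s in synapses], dtype=float)
    erev = np.array([s.e_rev for s in synapses], dtype=float)
    gated = np.array([1 if s.kind == "nmda" else 0 for s in synapses], dtype=np.int64)
    a1 = np.zeros(n)
    a2 = np.zeros(n)
    x0 = np.zeros(n)
    dx = np.ones(n)
    for i, s in enumerate(synapses):
        if s.boltzmann is not None:
            a1[i], a2[i], x0[i], dx[i] = s.boltzmann
    return tau, erev, gated, a1, a2, x0, dx


def _prepare_event_arrays(events: EventTrain, dt: float, n_steps: int, n_syn: int):
    if len(events) == 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=float),
        )
    steps = np.rint(events.onset_ms / dt).astype(np.int64)
    if np.any(steps < 0) or np.any(steps >= n_steps):
        raise ValueError("event onsets must lie within the simulation window")
    if np.any(events.synapse_id < 0) or np.any(events.synapse_id >= n_syn):
        raise ValueError("event synapse_id out of range for the synapse list")
    order = np.argsort(steps, kind="stable")
    return steps[order], events.synapse_id[order].astype(np.int64), events.weight_nS[order] * 1e-3


def steady_state_init(
    model: CompartmentModelSpec, settle_ms: float = 2000.0, tol_mV: float = 0.01
) -> InitialState:
    """Event-free settling of the model for ``settle_ms`` (default 2 s).

    Starts at the analytic fixed point estimate and integrates; raises if
    the final voltage still drifts, which signals unstable parameters.
    """
    v_start = resting_potential(model)
    m0, h0, n0 = steady_state_gates(v_start, model.kdr_shift)
    g_leak, e_leak, gna, ena, gk, ek = model.membrane_conductances_uS()
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty(0, dtype=float)
    n_steps = int(round(settle_ms / INTERNAL_DT_MS))
    v_rec, _, _, v, m, h, n, bad = _integrate(
        v_start, float(m0), float(h0), float(n0), INTERNAL_DT_MS, n_steps,
        model.c_nF, g_leak, e_leak, gna, ena, gk, ek, model.kdr_shift, model.active,
        empty_f, empty_f, empty_i, empty_f, empty_f, empty_f, np.ones(0),
        empty_i, empty_i, empty_f, empty_f,
        max(1, n_steps // 4), False,
    )
    if bad >= 0:
        raise RuntimeError("steady-state initialization diverged (unstable parameters)")
    drift = abs(v - v_rec[-1])
    if drift > tol_mV:
        raise RuntimeError(
            f"steady-state initialization did not converge (drift {drift:.4f} mV)"
        )
    return InitialState(v=float(v), m=float(m), h=float(h), n=float(n), drift_mV=float(drift))


def simulate_point_neuron(
    model: CompartmentModelSpec,
    synapses: Sequence[SynapseSpec],
    events: EventTrain,
    duration_ms: float,
    record_currents: bool = False,
    fine: bool = False,
    i_inj: Optional[Tuple[float, float, float] | np.ndarray] = None,
    internal_dt_ms: float = INTERNAL_DT_MS,
    init: Optional[InitialState] = None,
) -> VoltageTrace:
    """Integrate the point neuron under an event train.

    Parameters
    ----------
    i_inj : optional (amplitude_nA, start_ms, stop_ms) current step.
    fine : record at the internal time step instead of 1 kHz.
    internal_dt_ms : integration step (default 25 us).
    """
    dt = internal_dt_ms
    n_steps = int(round(duration_ms / dt))
    record_every = 1 if fine else max(1, int(round(1.0 / dt)))
    if init is None:
        init = steady_state_init(model)
    g_leak, e_leak, gna, ena, gk, ek = model.membrane_conductances_uS()
    tau, erev, gated, a1, a2, x0, dx = _prepare_synapse_arrays(synapses)
    ev_step, ev_syn, ev_w = _prepare_event_arrays(events, dt, max(n_steps, 1), len(synapses))
    inj = np.empty(0)
    if i_inj is not None:
        if isinstance(i_inj, tuple):
            amp, t0, t1 = i_inj
            inj = np.zeros(n_steps)
            inj[int(round(t0 / dt)) : int(round(t1 / dt))] = amp
        else:  # 1 kHz waveform in nA, held over each millisecond
            wave = np.asarray(i_inj, dtype=float)
            steps_per_ms = int(round(1.0 / dt))
            inj = np.repeat(wave, steps_per_ms)[:n_steps]
            if len(inj) < n_steps:
                inj = np.pad(inj, (0, n_steps - len(inj)))
    v_rec, ina, ik, *_rest, bad = _integrate(
        init.v, init.m, init.h, init.n, dt, n_steps,
        model.c_nF, g_leak, e_leak, gna, ena, gk, ek, model.kdr_shift, model.active,
        tau, erev, gated, a1, a2, x0, dx,
        ev_step, ev_syn, ev_w, inj,
        record_every, record_currents,
    )
    if bad >= 0:
        raise RuntimeError(
            f"integration produced a non-finite voltage at step {bad}; "
            "reduce the time step or check parameters"
        )
    return VoltageTrace(
        v=v_rec,
        dt_sample=dt * record_every,
        i_na=ina if record_currents else None,
        i_k=ik if record_currents else None,
        meta={"model": model, "duration_ms": duration_ms},
    )
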
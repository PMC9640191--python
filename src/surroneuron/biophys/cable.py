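"""A small multicompartment cable stand-in.

An unbranched chain: an active (or passive) soma at index 0 and a passive
dendritic cable, with synaptic sites mapped onto compartments.  This is an
intentionally simple surrogate for a reconstructed morphology -- it provides
somatic traces plus per-site event channels in the 201-row dataset format,
with cable attenuation and delay, but no branching or dendritic channels.
Voltage is advanced by an implicit Euler step (tridiagonal solve); gates and
synapses use the same exponential updates as the point model.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from numba import njit

from surroneuron.biophys.model import CompartmentModelSpec, SynapseSpec
from surroneuron.biophys.hh import steady_state_gates, resting_potential
from surroneuron.biophys.point import INTERNAL_DT_MS, _prepare_event_arrays
from surroneuron.events import EventTrain
from surroneuron.trace import VoltageTrace


@njit(cache=True)
def _rates_cable(v, kdr_shift):
    x = -(v + 40.0)
    am = 0.1 * (10.0 * (1.0 - x / 20.0) if abs(x / 10.0) < 1e-6 else x / (math.expm1(x / 10.0)))
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    vs = v - kdr_shift
    xn = -(vs + 55.0)
    an = 0.01 * (10.0 * (1.0 - xn / 20.0) if abs(xn / 10.0) < 1e-6 else xn / (math.expm1(xn / 10.0)))
    bn = 0.125 * math.exp(-(vs + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _integrate_cable(
    v,
    m,
    h,
    n,
    dt,
    n_steps,
    c_nF,
    g_pas,
    e_pas,
    soma_active,
    gna,
    ena,
    gk,
    ek,
    kdr_shift,
    g_ax,  # g_ax[i] couples compartments i-1 and i; g_ax[0] unused
    site_comp,
    site_tau,
    site_erev,
    ev_step,
    ev_site,
    ev_w_uS,
    record_every,
):
    ncomp = c_nF.shape[0]
    nsite = site_tau.shape[0]
    g_state = np.zeros(nsite)
    y_state = np.zeros(nsite)
    decay = np.empty(nsite)
    for s in range(nsite):
        decay[s] = math.exp(-dt / site_tau[s])

    n_rec = n_steps // record_every
    v_rec = np.empty(n_rec)
    lower = np.empty(ncomp)
    diag = np.empty(ncomp)
    upper = np.empty(ncomp)
    rhs = np.empty(ncomp)
    g_tot = np.empty(ncomp)
    ge_sum = np.empty(ncomp)

    ev_i = 0
    n_ev = ev_step.shape[0]
    rec_i = 0

    for step in range(n_steps):
        if step % record_every == 0 and rec_i < n_rec:
            v_rec[rec_i] = v[0]
            rec_i += 1

        while ev_i < n_ev and ev_step[ev_i] == step:
            s = ev_site[ev_i]
            y_state[s] += ev_w_uS[ev_i] * math.e / site_tau[s]
            ev_i += 1

        for s in range(nsite):
            g_state[s] = (g_state[s] + dt * y_state[s]) * decay[s]
            y_state[s] *= decay[s]

        if soma_active:
            am, bm, ah, bh, an, bn = _rates_cable(v[0], kdr_shift)
            sm = am + bm
            sh = ah + bh
            sn = an + bn
            m = am / sm + (m - am / sm) * math.exp(-dt * sm)
            h = ah / sh + (h - ah / sh) * math.exp(-dt * sh)
            n = an / sn + (n - an / sn) * math.exp(-dt * sn)

        for i in range(ncomp):
            g_tot[i] = g_pas[i]
            ge_sum[i] = g_pas[i] * e_pas[i]
        if soma_active:
            gna_t = gna * m * m * m * h
            gk_t = gk * n * n * n * n
            g_tot[0] += gna_t + gk_t
            ge_sum[0] += gna_t * ena + gk_t * ek
        for s in range(nsite):
            i = site_comp[s]
            g_tot[i] += g_state[s]
            ge_sum[i] += g_state[s] * site_erev[s]

        # assemble tridiagonal system for implicit Euler
        for i in range(ncomp):
            cap = c_nF[i] / dt
            b = cap + g_tot[i]
            a = 0.0
            c = 0.0
            if i > 0:
                a = -g_ax[i]
                b += g_ax[i]
            if i < ncomp - 1:
                c = -g_ax[i + 1]
                b += g_ax[i + 1]
            lower[i] = a
            diag[i] = b
            upper[i] = c
            rhs[i] = cap * v[i] + ge_sum[i]

        # Thomas algorithm
        for i in range(1, ncomp):
            w = lower[i] / diag[i - 1]
            diag[i] -= w * upper[i - 1]
            rhs[i] -= w * rhs[i - 1]
        v[ncomp - 1] = rhs[ncomp - 1] / diag[ncomp - 1]
        for i in range(ncomp - 2, -1, -1):
            v[i] = (rhs[i] - upper[i] * v[i + 1]) / diag[i]
        if not math.isfinite(v[0]):
            return v_rec[:rec_i], v, m, h, n, step
    return v_rec, v, m, h, n, -1


def default_site_map(n_compartments: int, synapse_sites: int) -> np.ndarray:
    """Spread sites evenly along the dendritic chain (all on the soma for a
    single-compartment cable)."""
    if n_compartments == 1:
        return np.zeros(synapse_sites, dtype=np.int64)
    return 1 + (np.arange(synapse_sites, dtype=np.int64) * (n_compartments - 1)) // synapse_sites


def simulate_cable_neuron(
    n_compartments: int,
    synapse_sites: int,
    model: CompartmentModelSpec,
    events: EventTrain,
    duration_ms: float,
    exc_spec: Optional[SynapseSpec] = None,
    inh_spec: Optional[SynapseSpec] = None,
    n_exc_sites: Optional[int] = None,
    dend_total_um: float = 500.0,
    dend_diam_um: float = 2.0,
    site_compartments: Optional[np.ndarray] = None,
    fine: bool = False,
    internal_dt_ms: float = INTERNAL_DT_MS,
    settle_ms: float = 2000.0,
) -> VoltageTrace:
    """Simulate the unbranched cable; returns the somatic trace.

    Event ``synapse_id`` indexes dendritic sites (0..synapse_sites-1); sites
    below ``n_exc_sites`` are excitatory, the rest inhibitory.  A
    single-compartment cable with one site is exactly the point model.
    """
    from surroneuron.biophys.model import excitatory_synapse, inhibitory_synapse

    if synapse_sites > 200:
        raise ValueError("at most 200 synaptic sites are supported")
    if exc_spec is None:
        exc_spec = excitatory_synapse()
    if inh_spec is None:
        inh_spec = inhibitory_synapse()
    if n_exc_sites is None:
        n_exc_sites = synapse_sites  # all excitatory by default
    if site_compartments is None:
        site_compartments = default_site_map(n_compartments, synapse_sites)
    site_compartments = np.asarray(site_compartments, dtype=np.int64)
    if site_compartments.shape[0] != synapse_sites:
        raise ValueError("site_compartments length must equal synapse_sites")
    if np.any(site_compartments < 0) or np.any(site_compartments >= n_compartments):
        raise IndexError("synapse site mapped to a compartment out of range")

    # geometry and passive properties
    c_nF = np.empty(n_compartments)
    g_pas = np.empty(n_compartments)
    e_pas = np.empty(n_compartments)
    soma_area = model.area_cm2
    c_nF[0] = model.c_nF
    g_leak, e_leak, gna, ena, gk, ek = model.membrane_conductances_uS()
    g_pas[0] = g_leak
    e_pas[0] = e_leak
    if n_compartments > 1:
        seg_len_um = dend_total_um / (n_compartments - 1)
        seg_area_cm2 = math.pi * dend_diam_um * seg_len_um * 1e-8
        c_nF[1:] = model.cm_uF_cm2 * seg_area_cm2 * 1e3
        g_pas[1:] = seg_area_cm2 / (model.rm_kohm_cm2 * 1e3) * 1e6
        e_pas[1:] = model.v_rest

    # axial conductances between adjacent compartments (uS)
    g_ax = np.zeros(n_compartments)
    if n_compartments > 1:
        seg_len_cm = (dend_total_um / (n_compartments - 1)) * 1e-4
        dend_xsec_cm2 = math.pi * (dend_diam_um * 1e-4 / 2.0) ** 2
        soma_len_cm = model.length_um * 1e-4
        soma_xsec_cm2 = math.pi * (model.diameter_um * 1e-4 / 2.0) ** 2
        r_half_dend = model.ri_ohm_cm * (seg_len_cm / 2.0) / dend_xsec_cm2  # Ohm
        r_half_soma = model.ri_ohm_cm * (soma_len_cm / 2.0) / soma_xsec_cm2
        g_ax[1] = 1e6 / (r_half_soma + r_half_dend)
        for i in range(2, n_compartments):
            g_ax[i] = 1e6 / (2.0 * r_half_dend)

    site_tau = np.empty(synapse_sites)
    site_erev = np.empty(synapse_sites)
    for s in range(synapse_sites):
        spec = exc_spec if s < n_exc_sites else inh_spec
        site_tau[s] = spec.tau_ms
        site_erev[s] = spec.e_rev

    dt = internal_dt_ms
    n_steps = int(round(duration_ms / dt))
    record_every = 1 if fine else max(1, int(round(1.0 / dt)))
    ev_step, ev_site, ev_w = _prepare_event_arrays(events, dt, max(n_steps, 1), synapse_sites)

    v0 = resting_potential(model)
    m0, h0, n0 = steady_state_gates(v0, model.kdr_shift)
    v = np.full(n_compartments, v0)
    v[1:] = model.v_rest if n_compartments > 1 else v0
    no_ev = np.empty(0, dtype=np.int64)
    no_w = np.empty(0, dtype=float)

    # settle to joint steady state before the stimulated run
    settle_steps = int(round(settle_ms / dt))
    _, v, m, h, n, bad = _integrate_cable(
        v, float(m0), float(h0), float(n0), dt, settle_steps,
        c_nF, g_pas, e_pas, model.active, gna, ena, gk, ek, model.kdr_shift, g_ax,
        site_compartments, site_tau, site_erev, no_ev, no_ev, no_w, settle_steps,
    )
    if bad >= 0:
        raise RuntimeError("cable settling diverged")

    v_rec, v, m, h, n, bad = _integrate_cable(
        v, m, h, n, dt, n_steps,
        c_nF, g_pas, e_pas, model.active, gna, ena, gk, ek, model.kdr_shift, g_ax,
        site_compartments, site_tau, site_erev, ev_step, ev_site, ev_w, record_every,
    )
    if bad >= 0:
        raise RuntimeError(f"cable integration produced a non-finite voltage at step {bad}")
    return VoltageTrace(
        v=v_rec,
        dt_sample=dt * record_every,
        meta={
            "model": model,
            "n_compartments": n_compartments,
            "site_compartments": site_compartments,
        },
    )
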
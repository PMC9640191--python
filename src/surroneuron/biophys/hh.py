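"""Hodgkin-Huxley channel kinetics (squid rate constants, 6.3 degrees C).

The delayed rectifier's voltage dependence can be shifted along the voltage
axis by evaluating its rates at (v - shift); a positive shift is rightward
(activation requires stronger depolarization).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / y / 2.0), x / (np.expm1(x / y) + 1e-300))
    return out


def rates_m(v):
    alpha = 0.1 * _vtrap(-(v + 40.0), 10.0)
    beta = 4.0 * np.exp(-(v + 65.0) / 18.0)
    return alpha, beta


def rates_h(v):
    alpha = 0.07 * np.exp(-(v + 65.0) / 20.0)
    beta = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    return alpha, beta


def rates_n(v, shift=0.0):
    vs = v - shift
    alpha = 0.01 * _vtrap(-(vs + 55.0), 10.0)
    beta = 0.125 * np.exp(-(vs + 65.0) / 80.0)
    return alpha, beta


def steady_state_gates(v, kdr_shift=0.0):
    """(m_inf, h_inf, n_inf) at a fixed voltage."""
    am, bm = rates_m(v)
    ah, bh = rates_h(v)
    an, bn = rates_n(v, kdr_shift)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def membrane_current_density(v, model):
    """Total steady-state membrane current density (mA/cm^2 scale) with gates
    at their voltage-clamped steady state.  Zero at the resting fixed point."""
    m, h, n = steady_state_gates(v, model.kdr_shift)
    g_leak, e_leak = model.leak_S_cm2()
    i = g_leak * (v - e_leak)
    i += model.gna_S_cm2 * m**3 * h * (v - model.e_na)
    i += model.gk_S_cm2 * n**4 * (v - model.e_k)
    return i


def resting_potential(model) -> float:
    """Resting fixed point of the model, by root-finding on the steady-state
    membrane current.  For passive models this is the leak anchor voltage."""
    if not model.active:
        return model.v_rest
    if model.gna_S_cm2 == 0 and model.gk_S_cm2 == 0:
        return model.leak_S_cm2()[1]
    return float(brentq(membrane_current_density, -90.0, -20.0, args=(model,), xtol=1e-10))
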
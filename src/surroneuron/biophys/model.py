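"""Compartment and synapse specifications.

The single-compartment reference cell is a 25 um x 25 um cylinder with
specific membrane resistance Rm = 1 kOhm*cm^2, Cm = 1 uF/cm^2 and axial
resistivity 35.4 Ohm*cm.  The active variant carries the classic mixed
Na/K/leak channel at densities gNa = 0.12, gK = 0.036 and gLeak = 0.0003
S/cm^2 with reversal potentials +50 / -77 / -54.3 mV.  The passive variant
uses only the Rm leak, anchored at the resting potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple


@dataclass(frozen=True)
class CompartmentModelSpec:
    """Geometry, passive properties and channel densities of one compartment.

    Conductance densities are in S/cm^2; reversal potentials in mV.
    ``kdr_shift`` moves the voltage dependence of the delayed-rectifier K+
    conductance along the voltage axis (positive = rightward/depolarized).
    """

    length_um: float = 25.0
    diameter_um: float = 25.0
    rm_kohm_cm2: float = 1.0
    cm_uF_cm2: float = 1.0
    ri_ohm_cm: float = 35.4
    v_rest: float = -70.0
    gna_S_cm2: float = 0.12
    gk_S_cm2: float = 0.036
    gleak_S_cm2: float = 0.0003
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.3
    active: bool = True
    kdr_shift: float = 0.0
    rm_leak: bool = True  # include the Rm-derived passive leak alongside the channels

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("length and diameter must be positive")
        if self.cm_uF_cm2 <= 0 or self.rm_kohm_cm2 <= 0:
            raise ValueError("Cm and Rm must be positive")
        for g in (self.gna_S_cm2, self.gk_S_cm2, self.gleak_S_cm2):
            if g < 0:
                raise ValueError("conductance densities must be non-negative")
        for e in (self.e_na, self.e_k, self.e_leak, self.v_rest):
            if not -120.0 <= e <= 80.0:
                raise ValueError("reversal/rest potentials must lie in [-120, 80] mV")

    @property
    def area_cm2(self) -> float:
        """Lateral (cylinder side) area, NEURON convention: pi * diam * L."""
        return math.pi * self.diameter_um * self.length_um * 1e-8

    @property
    def c_nF(self) -> float:
        return self.cm_uF_cm2 * self.area_cm2 * 1e3

    def density_to_uS(self, g_S_cm2: float) -> float:
        return g_S_cm2 * self.area_cm2 * 1e6

    @property
    def g_pas_S_cm2(self) -> float:
        return 1.0 / (self.rm_kohm_cm2 * 1e3)

    def leak_S_cm2(self) -> Tuple[float, float]:
        """Combined ohmic leak density and reversal.

        The Rm-derived passive leak (anchored at v_rest) is present in both
        the passive and the active cell; the active cell adds the channel
        set's own leak.  Two ohmic leaks fold exactly into one.
        """
        if not self.active:
            return self.g_pas_S_cm2, self.v_rest
        if not self.rm_leak:
            return self.gleak_S_cm2, self.e_leak
        g = self.g_pas_S_cm2 + self.gleak_S_cm2
        e = (self.g_pas_S_cm2 * self.v_rest + self.gleak_S_cm2 * self.e_leak) / g
        return g, e

    def membrane_conductances_uS(self) -> Tuple[float, float, float, float, float, float]:
        """(g_leak, e_leak, gna, ena, gk, ek) in uS / mV for this model."""
        g_leak, e_leak = self.leak_S_cm2()
        if self.active:
            return (
                self.density_to_uS(g_leak),
                e_leak,
                self.density_to_uS(self.gna_S_cm2),
                self.e_na,
                self.density_to_uS(self.gk_S_cm2),
                self.e_k,
            )
        return (self.density_to_uS(g_leak), e_leak, 0.0, self.e_na, 0.0, self.e_k)


@dataclass(frozen=True)
class SynapseSpec:
    """A conductance-based synapse with an alpha-function time course.

    ``kind`` is one of ``alpha_exc``, ``alpha_inh``, ``ampa`` or ``nmda``.
    The conductance transient is g(t) = w * (t/tau) * exp(1 - t/tau), peaking
    at the event weight w at tau after onset.  NMDA synapses additionally
    carry a Boltzmann voltage gate (A1, A2, x0, dx) that scales the
    conductance with the instantaneous membrane potential.
    """

    kind: str = "alpha_exc"
    tau_ms: float = 2.0
    gmax_nS: float = 2.5
    e_rev: float = 0.0
    boltzmann: Optional[Tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("alpha_exc", "alpha_inh", "ampa", "nmda"):
            raise ValueError(f"unknown synapse kind: {self.kind}")
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")
        if self.gmax_nS < 0:
            raise ValueError("gmax must be non-negative")
        if (self.kind == "nmda") != (self.boltzmann is not None):
            raise ValueError("boltzmann parameters present iff kind == 'nmda'")
        if self.boltzmann is not None and self.boltzmann[3] == 0:
            raise ValueError("boltzmann dx must be nonzero")


# -- canonical parameter sets -------------------------------------------------

#: Boltzmann gate of the NMDA conductance, voltage in mV.
NMDA_BOLTZMANN = (1.0, -1.0, -63.32, 0.013)


def passive_point_model(**overrides) -> CompartmentModelSpec:
    return CompartmentModelSpec(active=False, **overrides)


def active_point_model(**overrides) -> CompartmentModelSpec:
    return CompartmentModelSpec(active=True, **overrides)


def fast_spiking_model(**overrides) -> CompartmentModelSpec:
    """A fast-spiking phenotype: classic channel kinetics at halved densities
    (membrane time constant ~3 ms) and no extra Rm leak.  Rests near -65 mV
    and fires sustained, non-adapting ~50-65 Hz trains across the rising
    branch of its f-I curve before depolarization block."""
    defaults = dict(
        active=True, rm_leak=False,
        gna_S_cm2=0.07, gk_S_cm2=0.018, gleak_S_cm2=0.00015,
    )
    defaults.update(overrides)
    return CompartmentModelSpec(**defaults)


def excitatory_synapse(**overrides) -> SynapseSpec:
    defaults = dict(kind="alpha_exc", tau_ms=2.0, gmax_nS=2.5, e_rev=0.0)
    defaults.update(overrides)
    return SynapseSpec(**defaults)


def inhibitory_synapse(**overrides) -> SynapseSpec:
    defaults = dict(kind="alpha_inh", tau_ms=1.0, gmax_nS=8.0, e_rev=-90.0)
    defaults.update(overrides)
    return SynapseSpec(**defaults)


def ampa_synapse(**overrides) -> SynapseSpec:
    defaults = dict(kind="ampa", tau_ms=2.0, gmax_nS=2.5, e_rev=0.0)
    defaults.update(overrides)
    return SynapseSpec(**defaults)


def nmda_synapse(**overrides) -> SynapseSpec:
    defaults = dict(
        kind="nmda", tau_ms=10.0, gmax_nS=2.5, e_rev=0.0, boltzmann=NMDA_BOLTZMANN
    )
    defaults.update(overrides)
    return SynapseSpec(**defaults)
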
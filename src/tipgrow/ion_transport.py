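"""Transporter current kernels and stretch-channel gating.

Currents are per membrane area (A m^-2), outward positive.  Channel fluxes
use either the ohmic relationship ``I = g (V - E)`` or the
Goldman-Hodgkin-Katz constant-field relationship

    I = g V (ci - ce exp(-zV/Vref)) / (1 - exp(-zV/Vref))

which vanishes exactly at the ion's Nernst potential.  Stretch-activated
channels are two-state (open/closed) with a closed->open rate that grows
exponentially with turgor, ``kCO = kCO0 * exp(ka P)``, while ``kOC`` is
turgor-independent: rising turgor favours the open state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants
from .parameters import Parameters, ChannelKernel, ION_VALENCE

__all__ = [
    "GateState", "CurrentSet", "ohmic_current", "ghk_current",
    "nernst_potential", "stretch_gate_rates", "gate_rhs", "gate_equilibrium",
    "stretch_currents", "voltage_gated_currents", "membrane_potential_rhs",
    "boltzmann_gate",
]

_GHK_SMALL = 1e-6   # |zV/Vref| below which the series limit is used
_EXP_CLIP = 500.0   # exponent clip to stay inside float64 range
K_CO_MAX = 1.0e3    # s^-1; cap on the closed->open rate deep in saturation


@dataclass
class GateState:
    """Open fractions of the stretch-activated Ca2+ and K+ channels."""

    p_open_Ca: float
    p_open_K: float

    def __post_init__(self) -> None:
        for p in (self.p_open_Ca, self.p_open_K):
            if not (-1e-9 <= p <= 1.0 + 1e-9):
                raise ValueError("open fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CurrentSet:
    """Signed transporter currents (A m^-2, outward positive)."""

    I_vg1: float = 0.0   # K+ channel
    I_vg2: float = 0.0   # K+ channel
    I_vg3: float = 0.0   # Ca2+ channel
    I_vg4: float = 0.0   # H+ ATPase pump
    I_vg5: float = 0.0   # Cl-/2H+ symporter
    I_vg6: float = 0.0   # Cl- channel
    I_sa1: float = 0.0   # stretch-activated Ca2+
    I_sa2: float = 0.0   # stretch-activated K+
    I_sa3: float = 0.0   # optional stretch-activated Cl-

    def total(self) -> float:
        return (self.I_vg1 + self.I_vg2 + self.I_vg3 + self.I_vg4
                + self.I_vg5 + self.I_vg6 + self.I_sa1 + self.I_sa2
                + self.I_sa3)


def ohmic_current(g: float, V: float, E: float) -> float:
    """Ohmic transporter current ``g (V - E)``."""
    return g * (V - E)


def nernst_potential(z: int, ci: float, ce: float, Vref: float) -> float:
    """Nernst (reversal) potential ``(Vref/z) ln(ce/ci)``."""
    if z == 0:
        raise ValueError("valence z must be non-zero")
    if ci <= 0 or ce <= 0:
        raise ValueError("Nernst potential needs strictly positive concentrations")
    return (Vref / z) * math.log(ce / ci)


def ghk_current(g: float, V: float, z: int, ci: float, ce: float,
                Vref: float) -> float:
    """Goldman-Hodgkin-Katz constant-field current.

    Uses the series limit ``g Vref (ci - ce) / z`` for ``|zV/Vref| < 1e-6``
    to avoid the 0/0 at V = 0, and asymptotic forms for extreme voltages.
    """
    if z == 0:
        raise ValueError("valence z must be non-zero")
    if ci < 0 or ce < 0:
        raise ValueError("concentrations must be >= 0")
    x = z * V / Vref
    if abs(x) < _GHK_SMALL:
        return g * Vref * (ci - ce) / z
    if x > _EXP_CLIP:        # exp(-x) -> 0
        return g * V * ci
    if x < -_EXP_CLIP:       # exp(-x) dominates numerator and denominator
        return g * V * ce
    em = math.exp(-x)
    return g * V * (ci - ce * em) / (1.0 - em)


def boltzmann_gate(V: float, vhalf: float | None, slope: float) -> float:
    """Two-state Boltzmann voltage-gating factor ``1/(1+exp((V-vhalf)/slope))``."""
    if vhalf is None:
        return 1.0
    x = (V - vhalf) / slope
    if x > _EXP_CLIP:
        return 0.0
    if x < -_EXP_CLIP:
        return 1.0
    return 1.0 / (1.0 + math.exp(x))


def stretch_gate_rates(P: float, kOC0: float, kCO0: float,
                       ka: float) -> tuple[float, float]:
    """Gate transition rates at turgor ``P``: ``(kOC, kCO0 e^{ka P})``.

    Evaluated in log space so that steep activation (large ``ka``) paired
    with a tiny zero-turgor rate stays within float range.  The rate is
    capped at ``K_CO_MAX`` (1e3 s^-1): deep in saturation the open fraction
    is ~1 regardless, and an uncapped exponential would make the gate ODE
    arbitrarily stiff without changing the solution.
    """
    if not math.isfinite(P):
        raise ValueError("turgor must be finite")
    exponent = math.log(kCO0) + ka * P
    if exponent >= math.log(K_CO_MAX):
        return kOC0, K_CO_MAX
    return kOC0, math.exp(exponent)


def gate_rhs(p_open: float, kOC: float, kCO: float) -> float:
    """Mass-action open-fraction kinetics ``kCO (1-p) - kOC p``."""
    return kCO * (1.0 - p_open) - kOC * p_open


def gate_equilibrium(kOC: float, kCO: float) -> float:
    """Equilibrium open fraction ``kCO / (kCO + kOC)``."""
    return kCO / (kCO + kOC)


def _kernel_current(k: ChannelKernel, V: float, ions_i: dict, ions_o: dict,
                    Vref: float, gate_value: float | None = None) -> float:
    z = ION_VALENCE[k.ion]
    ci, ce = ions_i[k.ion], ions_o[k.ion]
    f = (gate_value if gate_value is not None
         else boltzmann_gate(V, k.vhalf, k.slope))
    if f == 0.0 or k.g == 0.0:
        return 0.0
    if k.kind == "ghk":
        return f * ghk_current(k.g, V, z, ci, ce, Vref)
    E = nernst_potential(z, ci, ce, Vref)
    return f * ohmic_current(k.g, V, E)


def stretch_currents(ions_i: dict, ions_o: dict, V: float, gates: GateState,
                     params: Parameters, constants: PhysicalConstants,
                     p_open_Cl: float = 0.0) -> tuple[float, float, float]:
    """Stretch-activated channel currents ``(I_sa1, I_sa2, I_sa3)``.

    Ca2+ (z=2) and K+ (z=1) use the GHK form scaled by the open fraction;
    the optional Cl- variant is off unless enabled in the parameters.
    """
    Vref = constants.Vref
    I_sa1 = gates.p_open_Ca * ghk_current(
        params.g_Ca_sa, V, 2, ions_i["Ca"], ions_o["Ca"], Vref)
    I_sa2 = gates.p_open_K * ghk_current(
        params.g_K_sa, V, 1, ions_i["K"], ions_o["K"], Vref)
    I_sa3 = 0.0
    if params.stretch_cl_enabled and params.g_Cl_sa > 0:
        I_sa3 = p_open_Cl * ghk_current(
            params.g_Cl_sa, V, -1, ions_i["Cl"], ions_o["Cl"], Vref)
    return I_sa1, I_sa2, I_sa3


def voltage_gated_currents(ions_i: dict, ions_o: dict, V: float,
                           params: Parameters,
                           constants: PhysicalConstants,
                           n_vg2: float | None = None) -> tuple[float, ...]:
    """Currents of the six voltage-gated transporters ``(Ivg1..Ivg6)``.

    Ivg1/Ivg2 carry K+, Ivg3 carries Ca2+, Ivg4 is the H+ pump (saturating
    efflux), Ivg5 the Cl-/2H+ symporter and Ivg6 a Cl- channel.  When the
    vg2 kernel has a gating time constant (``tau > 0``) its activation is
    the dynamic variable ``n_vg2`` instead of the instantaneous Boltzmann
    factor.
    """
    Vref = constants.Vref
    I1 = _kernel_current(params.vg1, V, ions_i, ions_o, Vref)
    gate2 = n_vg2 if (params.vg2.tau > 0 and n_vg2 is not None) else None
    I2 = _kernel_current(params.vg2, V, ions_i, ions_o, Vref,
                         gate_value=gate2)
    I3 = _kernel_current(params.vg3, V, ions_i, ions_o, Vref)
    # pump: outward-positive saturating efflux, more active when depolarized
    pk = params.pump
    x = -(V - pk.vhalf) / pk.slope
    if x > _EXP_CLIP:
        I4 = 0.0
    else:
        I4 = pk.imax / (1.0 + math.exp(x))
    # symporter: 2 H+ + 1 Cl- per cycle, net charge +1 inward when V < E_sym
    if params.symporter.g > 0:
        E_H = nernst_potential(1, ions_i["H"], ions_o["H"], Vref)
        E_Cl = nernst_potential(-1, ions_i["Cl"], ions_o["Cl"], Vref)
        E_sym = 2.0 * E_H - E_Cl
        I5 = ohmic_current(params.symporter.g, V, E_sym)
    else:
        I5 = 0.0
    I6 = _kernel_current(params.vg6, V, ions_i, ions_o, Vref)
    return I1, I2, I3, I4, I5, I6


def membrane_potential_rhs(currents: CurrentSet, Cm: float) -> float:
    """Charge balance: ``dV/dt = -(sum of signed currents) / Cm``."""
    if Cm <= 0:
        raise ValueError("membrane capacitance must be > 0")
    return -currents.total() / Cm
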
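"""Model parameters (strict SI units internally).

Pressures in Pa, lengths in m, volumes in m^3, times in s, concentrations in
M (mol L^-1; converted to mol m^-3 where the arithmetic needs it),
conductances per membrane area.

Only a handful of values are anchored in the literature (hydraulic
conductivity, the fusion-rate coefficient, radii and media osmolarities);
everything else is a calibration output recovered from the documented
experimental constraints (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal


KernelKind = Literal["ohmic", "ghk"]
IonName = Literal["Ca", "H", "K", "Cl"]

ION_VALENCE = {"Ca": 2, "H": 1, "K": 1, "Cl": -1}


@dataclass
class ChannelKernel:
    """Generic voltage-gated transporter kernel.

    The published kinetics of the six voltage-gated transporters are not
    restated here; each is a configurable ohmic or GHK kernel multiplied by
    a two-state Boltzmann gating factor ``1/(1 + exp((V - vhalf)/slope))``
    (``slope > 0`` activates on hyperpolarization, ``slope < 0`` on
    depolarization; ``vhalf=None`` disables gating).
    """

    kind: KernelKind = "ghk"
    ion: IonName = "K"
    g: float = 0.0               # A m^-2 V^-1 M^-1 (ghk) or S m^-2 (ohmic)
    vhalf: float | None = None   # V
    slope: float = 0.01          # V
    tau: float = 0.0             # s; >0 = first-order gating relaxation

    def validate(self) -> None:
        if self.g < 0:
            raise ValueError("channel conductance must be >= 0")
        if self.tau < 0:
            raise ValueError("gating time constant must be >= 0")
        if self.kind not in ("ohmic", "ghk"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.ion not in ION_VALENCE:
            raise ValueError(f"unknown ion {self.ion!r}")
        if self.slope == 0:
            raise ValueError("gating slope must be non-zero")


@dataclass
class PumpKernel:
    """H+ ATPase: saturating voltage-dependent efflux (outward positive)."""

    imax: float = 0.0            # A m^-2
    vhalf: float = -0.15         # V
    slope: float = 0.02          # V

    def validate(self) -> None:
        if self.imax < 0:
            raise ValueError("pump imax must be >= 0")
        if self.slope <= 0:
            raise ValueError("pump slope must be > 0")


@dataclass
class SymporterKernel:
    """Cl- / 2H+ symporter, ohmic-type with a combined reversal potential.

    One transport cycle moves 2 H+ and 1 Cl- inward (net charge +1 in), so
    the reversal potential is ``2*E_H - E_Cl`` and the H+ equation receives
    twice the symporter current that the Cl- equation does.
    """

    g: float = 0.0               # S m^-2

    def validate(self) -> None:
        if self.g < 0:
            raise ValueError("symporter conductance must be >= 0")


@dataclass
class Parameters:
    # hydrodynamics
    Lp: float = 1.0e-12          # m s^-1 Pa^-1 (literature: 1e-6 m/s/MPa)
    A_osm: float = 1.13e-11      # m^2, osmotic-zone membrane area at tip
    eps: float = 3.0e6           # Pa, volumetric elastic modulus
    Pc: float = 0.195e6          # Pa, critical (yield) turgor
    v_ext: float = 5.1e-15       # m^3, extensible tip-region volume
    Osm_i: float = 0.5           # M, non-ionic cellular osmolyte pool

    osmolyte_dynamic: bool = True  # conserved osmolyte pool vs direct control

    # wall mechanics (eta_eq listed here; scenario protocols may override it)
    eta_eq: float = 25.0e6       # Pa s, equilibrium wall viscosity
    k1: float = 0.02             # s^-1, viscosity relaxation rate
    k2a: float = 2.15e-14        # m^3 M^-1 s^-1, fusion-rate coefficient

    # stretch-activated channel gating
    kOC0: float = 0.5            # s^-1, open->closed rate (turgor-independent)
    kCO0: float = 1.0e-20        # s^-1, closed->open rate at zero turgor
    ka: float = 2.0e-4           # Pa^-1, pressure-activation strength
    g_Ca_sa: float = 0.05        # A m^-2 V^-1 M^-1, stretch Ca2+ channel
    g_K_sa: float = 0.5          # A m^-2 V^-1 M^-1, stretch K+ channel
    stretch_cl_enabled: bool = False   # optional stretch Cl- channel variant
    g_Cl_sa: float = 0.0

    # voltage-gated transporter set (Ivg1..Ivg6)
    vg1: ChannelKernel = field(default_factory=lambda: ChannelKernel(
        kind="ghk", ion="K", g=2.0, vhalf=-0.14, slope=0.01))
    vg2: ChannelKernel = field(default_factory=lambda: ChannelKernel(
        kind="ghk", ion="K", g=2.0, vhalf=-0.06, slope=-0.01))
    vg3: ChannelKernel = field(default_factory=lambda: ChannelKernel(
        kind="ghk", ion="Ca", g=0.05, vhalf=-0.12, slope=0.008))
    pump: PumpKernel = field(default_factory=lambda: PumpKernel(
        imax=0.05, vhalf=-0.15, slope=0.02))
    symporter: SymporterKernel = field(default_factory=lambda: SymporterKernel(
        g=0.05))
    vg6: ChannelKernel = field(default_factory=lambda: ChannelKernel(
        kind="ohmic", ion="Cl", g=0.05, vhalf=None))

    # ion relaxation to shank set-points and buffering
    k_relax_Ca: float = 0.3      # s^-1
    k_relax_H: float = 0.5
    k_relax_K: float = 0.05
    k_relax_Cl: float = 0.05
    setpoint_Ca: float = 2.0e-7  # M
    setpoint_H: float = 1.0e-7   # M (pH 7.0)
    setpoint_K: float = 0.055    # M
    setpoint_Cl: float = 0.012   # M
    buffer_strength_Ca: float = 0.0   # s^-1, linear stand-in (off by default)
    buffer_strength_H: float = 0.0

    # membrane
    Cm: float = 0.01             # F m^-2

    # geometry
    r0: float = 5.0e-6           # m, outer radius
    ri0: float = 4.7e-6          # m, inner radius
    L0: float = 500.0e-6         # m, initial length
    h0: float = 0.3e-6           # m, wall thickness

    def validate(self) -> None:
        positive = [
            "Lp", "A_osm", "eps", "Pc", "v_ext", "Osm_i", "eta_eq", "k1",
            "kOC0", "kCO0", "Cm", "r0", "ri0", "L0", "h0",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0")
        nonneg = [
            "k2a", "ka", "g_Ca_sa", "g_K_sa", "g_Cl_sa",
            "k_relax_Ca", "k_relax_H", "k_relax_K", "k_relax_Cl",
            "setpoint_Ca", "setpoint_H", "setpoint_K", "setpoint_Cl",
            "buffer_strength_Ca", "buffer_strength_H",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0")
        if not self.ri0 < self.r0:
            raise ValueError("inner radius ri0 must be smaller than r0")
        if abs((self.r0 - self.ri0) - self.h0) > 0.5 * self.h0:
            raise ValueError("h0 should be consistent with r0 - ri0")
        for kernel in (self.vg1, self.vg2, self.vg3, self.vg6):
            kernel.validate()
        self.pump.validate()
        self.symporter.validate()

    def copy(self, **changes) -> "Parameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        d = dict(d)
        for name, kcls in (("vg1", ChannelKernel), ("vg2", ChannelKernel),
                           ("vg3", ChannelKernel), ("vg6", ChannelKernel),
                           ("pump", PumpKernel),
                           ("symporter", SymporterKernel)):
            if name in d and isinstance(d[name], dict):
                d[name] = kcls(**d[name])
        p = cls(**d)
        p.validate()
        return p
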
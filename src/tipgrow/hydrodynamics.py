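"""Osmotic water flow, Lockhart wall extension and the turgor balance.

Water enters through the fixed osmotic zone at the tip:

    dv/dt (water)  = Lp A_osm ((pi_i - pi_o) - P)

The wall chamber yields plastically above the critical turgor Pc only in
the extensible tip region, plus an elastic term:

    (1/v) dv/dt (chamber) = (v_ext/v) phi max(P - Pc, 0) + (1/eps) dP/dt

Because the water volume and the wall-chamber volume of the cell are the
same, equality of the two relative rates yields the turgor ODE:

    dP/dt = eps ( (Lp A_osm / v)(pi_i - pi_o - P)
                  - (v_ext / v) phi max(P - Pc, 0) )

Turgor therefore plays two opposing roles: it pushes water out
(d(water rate)/dP < 0) and extends the wall (d(chamber rate)/dP > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HydroState", "FluxBreakdown", "osmotic_pressure", "water_volume_rate",
    "wall_chamber_rate", "turgor_rhs", "turgor_fixed_point",
    "growth_rate_from_volume",
]


@dataclass
class HydroState:
    v: float   # m^3
    P: float   # Pa, relative to media
    L: float   # m

    def __post_init__(self) -> None:
        if self.v <= 0 or self.L <= 0:
            raise ValueError("volume and length must be > 0")


@dataclass(frozen=True)
class FluxBreakdown:
    """Water-flux decomposition and derived rates at one instant."""

    osmotic_inflow: float     # Lp A_osm (pi_i - pi_o), m^3 s^-1
    turgor_outflow: float     # Lp A_osm P, m^3 s^-1
    net_water: float          # m^3 s^-1
    wall_chamber_rate: float  # m^3 s^-1
    growth_rate: float        # dL/dt, m s^-1


def osmotic_pressure(Ca: float, H: float, K: float, Cl: float,
                     Osm_other: float, R: float, T: float) -> float:
    """Van 't Hoff osmotic pressure ``RT * sum(c)`` (concentrations in M)."""
    for c in (Ca, H, K, Cl, Osm_other):
        if c < 0:
            raise ValueError("concentrations must be >= 0")
    total_mol_m3 = (Ca + H + K + Cl + Osm_other) * 1.0e3
    return R * T * total_mol_m3


def water_volume_rate(v: float, P: float, pi_i: float, pi_o: float,
                      Lp: float, A_osm: float) -> tuple[float, float, float]:
    """Water-side fluxes ``(osmotic_inflow, turgor_outflow, net)`` in m^3/s.

    ``A_osm`` is the fixed tip osmotic-zone area; it does not scale with
    the cell volume, which is what prevents exponential growth.
    """
    if v <= 0:
        raise ValueError("volume must be > 0")
    osmotic_inflow = Lp * A_osm * (pi_i - pi_o)
    turgor_outflow = Lp * A_osm * P
    return osmotic_inflow, turgor_outflow, osmotic_inflow - turgor_outflow


def wall_chamber_rate(v: float, v_ext: float, phi: float, P: float,
                      Pc: float, eps: float, dP_dt: float) -> float:
    """Chamber-side volume rate dv/dt = v_ext phi max(P-Pc,0) + (v/eps) dP/dt."""
    if v <= 0:
        raise ValueError("volume must be > 0")
    if phi < 0:
        raise ValueError("extensibility must be >= 0")
    plastic = v_ext * phi * max(P - Pc, 0.0)
    elastic = v / eps * dP_dt
    return plastic + elastic


def turgor_rhs(v: float, P: float, pi_i: float, pi_o: float, phi: float,
               Lp: float, A_osm: float, v_ext: float, Pc: float,
               eps: float) -> float:
    """Turgor ODE from equality of water and chamber relative rates."""
    if v <= 0:
        raise ValueError("volume must be > 0")
    water_rel = Lp * A_osm / v * (pi_i - pi_o - P)
    plastic_rel = v_ext / v * phi * max(P - Pc, 0.0)
    return eps * (water_rel - plastic_rel)


def turgor_fixed_point(pi_i: float, pi_o: float, phi: float, Lp: float,
                       A_osm: float, v_ext: float, Pc: float) -> float:
    """Steady turgor at frozen osmotic pressures and extensibility.

    Root of ``Lp A_osm (dpi - P) = v_ext phi (P - Pc)`` when it lies above
    Pc, otherwise the osmotic equilibrium ``P = dpi``.
    """
    dpi = pi_i - pi_o
    lpa = Lp * A_osm
    w = v_ext * phi
    P = (lpa * dpi + w * Pc) / (lpa + w)
    if P < Pc:
        P = dpi
    return P


def growth_rate_from_volume(dv_dt: float, r: float, dr_dt: float,
                            L: float) -> float:
    """Convert volume change of a cylinder into length growth rate.

    ``dL/dt = (dv/dt - 2 pi r L dr/dt) / (pi r^2)``; reduces to
    ``dv/dt / (pi r^2)`` at fixed radius.
    """
    if r <= 0:
        raise ValueError("radius must be > 0")
    return (dv_dt - 2.0 * math.pi * r * L * dr_dt) / (math.pi * r * r)
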
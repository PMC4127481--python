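"""Cell-wall viscosity, secretion and wall-thickness dynamics.

Fresh vesicle material softens the wall (lowers its viscosity) while
relaxation pulls the viscosity back toward its equilibrium value:

    d(eta)/dt = -eta * Rs / h + k1 * (eta_eq - eta)

Vesicle secretion is linear in tip calcium, ``Rs = k2 [Ca2+]_i`` with
``k2 = k2a / r^2``.  Wall thickness thins with axial growth and thickens
with secretion:

    dh/dt = -3 (r^2 - ri^2) / (2 r^2) * dL/dt + Rs

Extensibility is the reciprocal viscosity, ``phi = 1/eta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

H_MIN = 1.0e-9  # m; thickness floor inside the RHS (avoids division blow-up)


@dataclass
class WallState:
    eta: float   # Pa s
    h: float     # m

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("wall viscosity must be > 0")
        if self.h <= 0:
            raise ValueError("wall thickness must be > 0")


def secretion_rate(Ca_i: float, k2: float) -> float:
    """Vesicle secretion rate to the wall, ``Rs = k2 [Ca2+]_i`` (m s^-1)."""
    if Ca_i < 0:
        raise ValueError("Ca_i must be >= 0")
    return k2 * Ca_i


def k2_from_radius(k2a: float, r: float) -> float:
    """Radius scaling of the secretion coefficient, ``k2 = k2a / r^2``."""
    if r <= 0:
        raise ValueError("radius must be > 0")
    return k2a / (r * r)


def viscosity_rhs(eta: float, Rs: float, h: float, eta_eq: float,
                  k1: float) -> float:
    """Wall viscosity dynamics: secretion softens, relaxation restores."""
    if h <= 0:
        raise ValueError("wall thickness must be > 0")
    if h < H_MIN:
        warnings.warn("wall thickness below 1 nm; clipped in viscosity RHS",
                      RuntimeWarning, stacklevel=2)
        h = H_MIN
    return -eta * Rs / h + k1 * (eta_eq - eta)


def viscosity_fixed_point(Rs: float, h: float, eta_eq: float,
                          k1: float) -> float:
    """Steady viscosity ``eta* = k1 eta_eq / (k1 + Rs/h)`` at constant inputs."""
    return k1 * eta_eq / (k1 + Rs / h)


def extensibility(eta: float) -> float:
    """Wall extensibility, the inverse viscosity (Pa^-1 s^-1)."""
    if eta <= 0:
        raise ValueError("viscosity must be > 0 to define extensibility")
    return 1.0 / eta


def thickness_rhs(r: float, r_i: float, dL_dt: float, Rs: float) -> float:
    """Wall-thickness dynamics: growth thins, secretion thickens."""
    if not 0 < r_i < r:
        raise ValueError("inner radius must satisfy 0 < r_i < r")
    return -3.0 * (r * r - r_i * r_i) / (2.0 * r * r) * dL_dt + Rs
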
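"""Cellular ion concentration dynamics.

Each of the four cellular ions obeys

    d[X]_i/dt = -OV * (current sum)/(z F)  -  k_X ([X]_i - [X]_s)
                -  ((1/v) dv/dt) [X]_i     +  buffering (Ca2+, H+ only)

where OV is the transporter surface-to-volume ratio (2/r for a cylinder).
Only the product of OV and the membrane conductances matters, so scaling
OV up and all conductances down by the same factor leaves the ion dynamics
unchanged.  The buffering terms are linear relaxations toward the same
set-points with a configurable strength (zero by default, i.e. folded into
the relaxation terms).
"""

from __future__ import annotations

from dataclasses import dataclass

from .ion_transport import CurrentSet
from .parameters import Parameters

# ion currents are A m^-2 -> mol m^-3 s^-1 via OV/(zF); /1e3 converts to M/s
_M3_TO_L = 1.0e3


@dataclass
class IonState:
    Ca_i: float
    H_i: float
    K_i: float
    Cl_i: float

    def __post_init__(self) -> None:
        for c in (self.Ca_i, self.H_i, self.K_i, self.Cl_i):
            if c < 0:
                raise ValueError("ion concentrations must be >= 0")


def ion_rhs(ions: IonState, currents: CurrentSet, OV: float, F: float,
            rel_vol_rate: float,
            params: Parameters) -> tuple[float, float, float, float]:
    """Time derivatives (M s^-1) of [Ca2+]_i, [H+]_i, [K+]_i, [Cl-]_i."""
    if min(ions.Ca_i, ions.H_i, ions.K_i, ions.Cl_i) < 0:
        raise ValueError("negative ion concentration")
    c = currents
    flux_Ca = -OV * (c.I_vg3 + c.I_sa1) / (2.0 * F) / _M3_TO_L
    flux_H = -OV * (c.I_vg4 + 2.0 * c.I_vg5) / F / _M3_TO_L
    flux_K = -OV * (c.I_vg1 + c.I_vg2 + c.I_sa2) / F / _M3_TO_L
    flux_Cl = -OV * (-c.I_vg6 + c.I_vg5 + c.I_sa3) / F / _M3_TO_L

    d_Ca = (flux_Ca - params.k_relax_Ca * (ions.Ca_i - params.setpoint_Ca)
            - rel_vol_rate * ions.Ca_i
            - params.buffer_strength_Ca * (ions.Ca_i - params.setpoint_Ca))
    d_H = (flux_H - params.k_relax_H * (ions.H_i - params.setpoint_H)
           - rel_vol_rate * ions.H_i
           - params.buffer_strength_H * (ions.H_i - params.setpoint_H))
    d_K = (flux_K - params.k_relax_K * (ions.K_i - params.setpoint_K)
           - rel_vol_rate * ions.K_i)
    d_Cl = (flux_Cl - params.k_relax_Cl * (ions.Cl_i - params.setpoint_Cl)
            - rel_vol_rate * ions.Cl_i)
    return d_Ca, d_H, d_K, d_Cl
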
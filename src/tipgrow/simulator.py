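"""Full model assembly and integration.

The dynamical state has 14 components: cell volume v, turgor P, length L,
wall viscosity eta, wall thickness h, four cellular ion concentrations,
membrane voltage V_m, the two stretch-channel open fractions and the slow
activation gate of the outward K+ rectifier (n_vg2, used when that kernel
has a non-zero gating time constant) and the non-ionic osmolyte pool
(Osm_i; tracks the protocol supply while growing, concentrates under
water loss).  The
water volume is integrated (the chamber side follows from the turgor
balance identity and is recovered for diagnostics, not double-integrated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import PhysicalConstants, DEFAULT_CONSTANTS
from .parameters import Parameters
from .protocol import ScenarioProtocol
from . import ion_transport as it
from . import wall_mechanics as wm
from .ion_dynamics import ion_rhs, IonState
from .ion_transport import CurrentSet, GateState

__all__ = ["CellState", "Trajectory", "SolverSettings", "SimulationError",
           "run_simulation", "initial_state", "STATE_NAMES"]

STATE_NAMES = ["v", "P", "L", "eta", "h", "Ca_i", "H_i", "K_i", "Cl_i",
               "V_m", "p_open_Ca", "p_open_K", "n_vg2", "Osm_i"]


class SimulationError(RuntimeError):
    pass


@dataclass
class CellState:
    v: float
    P: float
    L: float
    eta: float
    h: float
    Ca_i: float
    H_i: float
    K_i: float
    Cl_i: float
    V_m: float
    p_open_Ca: float
    p_open_K: float
    n_vg2: float = 1.0
    Osm_i: float = 0.5

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SolverSettings:
    rtol: float = 1.0e-8
    dt_sample: float = 0.1      # s, dense-output sampling interval
    method: str = "LSODA"
    max_step: float = np.inf
    # per-state absolute tolerances are rtol-scaled typical magnitudes
    atol_scale: dict = field(default_factory=lambda: {
        "v": 1e-14, "P": 1e5, "L": 1e-4, "eta": 1e7, "h": 1e-7,
        "Ca_i": 1e-6, "H_i": 1e-7, "K_i": 1e-2, "Cl_i": 1e-2,
        "V_m": 1e-1, "p_open_Ca": 1e0, "p_open_K": 1e0, "n_vg2": 1e0,
        "Osm_i": 1e0,
    })

    def atol_vector(self) -> np.ndarray:
        return np.array([self.rtol * self.atol_scale[n] for n in STATE_NAMES])


def initial_state(params: Parameters, protocol: ScenarioProtocol,
                  constants: PhysicalConstants = DEFAULT_CONSTANTS,
                  t0: float | None = None, P0: float = 0.2e6,
                  V_m0: float = -0.1,
                  overrides: dict | None = None) -> CellState:
    """Cold-start state: set-point ions, equilibrium wall and gates."""
    if t0 is None:
        t0 = protocol.t_span[0]
    ext = protocol.at(t0)
    kOC, kCO = it.stretch_gate_rates(P0, params.kOC0, params.kCO0, params.ka)
    p_eq = it.gate_equilibrium(kOC, kCO)
    state = CellState(
        v=math.pi * ext.r ** 2 * params.L0, P=P0, L=params.L0,
        eta=ext.eta_eq, h=params.h0,
        Ca_i=params.setpoint_Ca, H_i=params.setpoint_H,
        K_i=params.setpoint_K, Cl_i=params.setpoint_Cl,
        V_m=V_m0, p_open_Ca=p_eq, p_open_K=p_eq,
        n_vg2=it.boltzmann_gate(V_m0, params.vg2.vhalf, params.vg2.slope),
        Osm_i=ext.Osm_i,
    )
    if overrides:
        for key, val in overrides.items():
            if key not in STATE_NAMES:
                raise ValueError(f"unknown state component {key!r}")
            setattr(state, key, float(val))
        # volume must stay consistent with the protocol radius and length
        state.v = math.pi * ext.r ** 2 * state.L
    return state


def _rhs(t: float, y: np.ndarray, params: Parameters,
         constants: PhysicalConstants, protocol: ScenarioProtocol
         ) -> np.ndarray:
    (v, P, L, eta, h, Ca, H, K, Cl, Vm, pCa, pK, n2, Osm) = y
    ext = protocol.at(t)
    r = ext.r
    # solver iterates may make small negative excursions; evaluate the
    # physics on the clipped values (trajectories themselves stay positive)
    Ca_c, H_c, K_c, Cl_c = (max(Ca, 0.0), max(H, 0.0),
                            max(K, 0.0), max(Cl, 0.0))
    h_eff = max(h, wm.H_MIN)
    eta_eff = max(eta, 1.0)
    v_eff = max(v, 1e-20)

    ions_i = {"Ca": Ca_c, "H": H_c, "K": K_c, "Cl": Cl_c}
    ions_o = {"Ca": ext.Ca_o, "H": ext.H_o, "K": ext.K_o, "Cl": ext.Cl_o}

    Osm_c = max(Osm, 0.0)
    RT = constants.RT
    pi_i = RT * 1e3 * (Ca_c + H_c + K_c + Cl_c + Osm_c)
    pi_o = RT * 1e3 * (ext.Ca_o + ext.H_o + ext.K_o + ext.Cl_o + ext.Osm_o)

    dv = params.Lp * params.A_osm * (pi_i - pi_o - P)
    rel = dv / v_eff
    # non-ionic osmolyte pool: delivered with new cytoplasm at the supply
    # concentration while growing, concentrated 1:1 by water loss while
    # shrinking; or slaved to the protocol course (oil-injection semantics)
    if params.osmolyte_dynamic:
        d_osm = rel * (ext.Osm_i - Osm_c) if rel >= 0.0 else -rel * Osm_c
    else:
        d_osm = (ext.Osm_i - Osm_c) / 10.0
    dL = (dv - 2.0 * math.pi * r * L * ext.dr_dt) / (math.pi * r * r)
    phi = 1.0 / eta_eff
    plastic_rel = params.v_ext / v_eff * phi * max(P - params.Pc, 0.0)
    dP = params.eps * (rel - plastic_rel)

    k2 = ext.fusion_scale * params.k2a / (r * r)
    Rs = k2 * Ca_c
    d_eta = -eta_eff * Rs / h_eff + params.k1 * (ext.eta_eq - eta_eff)
    ri = max(r - h_eff, 0.05 * r)
    dh = -3.0 * (r * r - ri * ri) / (2.0 * r * r) * dL + Rs

    kOC, kCO = it.stretch_gate_rates(P, params.kOC0, params.kCO0, params.ka)
    pCa_c = min(max(pCa, 0.0), 1.0)
    pK_c = min(max(pK, 0.0), 1.0)
    d_pCa = it.gate_rhs(pCa_c, kOC, kCO)
    d_pK = it.gate_rhs(pK_c, kOC, kCO)

    gates = GateState.__new__(GateState)  # skip validation in hot loop
    gates.p_open_Ca, gates.p_open_K = pCa_c, pK_c
    I_sa1, I_sa2, I_sa3 = it.stretch_currents(
        ions_i, ions_o, Vm, gates, params, constants, p_open_Cl=pK_c)
    n2_c = min(max(n2, 0.0), 1.0)
    I1, I2, I3, I4, I5, I6 = it.voltage_gated_currents(
        ions_i, ions_o, Vm, params, constants, n_vg2=n2_c)
    if params.vg2.tau > 0:
        n2_inf = it.boltzmann_gate(Vm, params.vg2.vhalf, params.vg2.slope)
        d_n2 = (n2_inf - n2_c) / params.vg2.tau
    else:
        d_n2 = 0.0
    currents = CurrentSet(I1, I2, I3, I4, I5, I6, I_sa1, I_sa2, I_sa3)

    OV = 2.0 / r
    ion_state = IonState.__new__(IonState)
    ion_state.Ca_i, ion_state.H_i = Ca_c, H_c
    ion_state.K_i, ion_state.Cl_i = K_c, Cl_c
    d_Ca, d_H, d_K, d_Cl = ion_rhs(ion_state, currents, OV, constants.F,
                                   rel, params)
    d_Vm = it.membrane_potential_rhs(currents, params.Cm)

    return np.array([dv, dP, dL, d_eta, dh, d_Ca, d_H, d_K, d_Cl,
                     d_Vm, d_pCa, d_pK, d_n2, d_osm])


@dataclass
class Trajectory:
    """Dense time series of the state plus derived fluxes.

    ``data`` columns: the 14 state components, the protocol radius ``r``,
    osmotic pressures ``pi_i``/``pi_o`` (Pa), extensibility ``phi``
    (Pa^-1 s^-1), the water-flux breakdown (m^3 s^-1), turgor rate ``dP_dt``
    (Pa s^-1) and convenience columns ``growth_rate_um_min`` and
    ``dvdt_um3_s``.
    """

    t: np.ndarray
    data: pd.DataFrame
    params: Parameters
    protocol_name: str = "custom"

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def final_state(self) -> CellState:
        row = self.data.iloc[-1]
        return CellState(**{n: float(row[n]) for n in STATE_NAMES})

    def flux_balance_residual(self) -> np.ndarray:
        """Constitutive turgor identity residual, per sample.

        ``eps * (water relative rate - plastic chamber relative rate)``
        must equal ``dP/dt``; equivalently the full chamber rate (plastic
        plus elastic) must equal the water rate.
        """
        d = self.data
        v = d["v"].to_numpy()
        eps = self.params.eps
        dP_dt = d["dP_dt"].to_numpy()
        water_rel = d["net_water"].to_numpy() / v
        plastic_rel = (d["wall_chamber_rate"].to_numpy() / v
                       - dP_dt / eps)
        return eps * (water_rel - plastic_rel) - dP_dt


def _derived_frame(t: np.ndarray, states: np.ndarray, params: Parameters,
                   constants: PhysicalConstants,
                   protocol: ScenarioProtocol) -> pd.DataFrame:
    df = pd.DataFrame(states.T, columns=STATE_NAMES)
    df.insert(0, "t", t)
    courses = {k: np.array([c(x) for x in t])
               for k, c in protocol.courses.items()}
    drdt = np.array([protocol.courses["r"].slope(x) for x in t])
    r = courses["r"]
    RT = constants.RT
    pi_i = RT * 1e3 * (df["Ca_i"] + df["H_i"] + df["K_i"] + df["Cl_i"]
                       + df["Osm_i"])
    pi_o = RT * 1e3 * (courses["Ca_o"] + courses["H_o"] + courses["K_o"]
                       + courses["Cl_o"] + courses["Osm_o"])
    df["r"] = r
    df["pi_i"] = pi_i
    df["pi_o"] = pi_o
    df["phi"] = 1.0 / df["eta"]
    lpa = params.Lp * params.A_osm
    df["osmotic_inflow"] = lpa * (pi_i - pi_o)
    df["turgor_outflow"] = lpa * df["P"]
    df["net_water"] = df["osmotic_inflow"] - df["turgor_outflow"]
    plastic_rel = (params.v_ext / df["v"] * df["phi"]
                   * np.maximum(df["P"] - params.Pc, 0.0))
    water_rel = df["net_water"] / df["v"]
    df["dP_dt"] = params.eps * (water_rel - plastic_rel)
    df["wall_chamber_rate"] = (plastic_rel * df["v"]
                               + df["v"] / params.eps * df["dP_dt"])
    df["growth_rate"] = ((df["net_water"] - 2 * np.pi * r * df["L"] * drdt)
                         / (np.pi * r ** 2))
    df["growth_rate_um_min"] = df["growth_rate"] * 6.0e7
    df["dvdt_um3_s"] = df["net_water"] * 1e18
    return df


def run_simulation(params: Parameters, protocol: ScenarioProtocol,
                   t_span: tuple[float, float],
                   settings: SolverSettings | None = None,
                   init: CellState | None = None,
                   constants: PhysicalConstants = DEFAULT_CONSTANTS
                   ) -> Trajectory:
    """Integrate the full model over ``t_span`` under a scenario protocol.

    The integration restarts at every protocol breakpoint so the solver
    never steps across a kink in the forcing.  Output is sampled densely at
    ``settings.dt_sample``.  Deterministic: identical inputs give identical
    trajectories.
    """
    settings = settings or SolverSettings()
    span0, span1 = protocol.t_span
    if t_span[0] < span0 - 1e-9 or t_span[1] > span1 + 1e-9:
        raise ValueError(f"t_span {t_span} outside protocol span "
                         f"[{span0}, {span1}]")
    if init is None:
        init = initial_state(params, protocol, constants, t0=t_span[0])
    params.validate()

    breaks = protocol.breakpoints()
    breaks = breaks[(breaks > t_span[0]) & (breaks < t_span[1])]
    edges = np.concatenate([[t_span[0]], breaks, [t_span[1]]])

    y0 = init.to_array()
    atol = settings.atol_vector()
    t_chunks: list[np.ndarray] = []
    y_chunks: list[np.ndarray] = []
    n_total = int(round((t_span[1] - t_span[0]) / settings.dt_sample))
    t_eval_all = t_span[0] + settings.dt_sample * np.arange(n_total + 1)

    for a, b in zip(edges[:-1], edges[1:]):
        mask = (t_eval_all >= a - 1e-9) & (t_eval_all <= b + 1e-9)
        t_eval = t_eval_all[mask]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            _rhs, (a, b), y0, method=settings.method, t_eval=t_eval,
            rtol=settings.rtol, atol=atol, max_step=settings.max_step,
            args=(params, constants, protocol), dense_output=False)
        if not sol.success:
            worst = STATE_NAMES[int(np.argmax(np.abs(
                _rhs(sol.t[-1], sol.y[:, -1], params, constants, protocol))))]
            raise SimulationError(
                f"integration failed at t={sol.t[-1]:.3f} s "
                f"(fastest-moving state: {worst}): {sol.message}")
        keep = slice(0, -1) if b < edges[-1] else slice(None)
        t_chunks.append(sol.t[keep])
        y_chunks.append(sol.y[:, keep])
        y0 = sol.y[:, -1]

    t = np.concatenate(t_chunks)
    y = np.concatenate(y_chunks, axis=1)
    # drop the helper points inserted at chunk edges, keep strictly increasing
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, y = t[keep], y[:, keep]
    df = _derived_frame(t, y, params, constants, protocol)
    return Trajectory(t=t, data=df, params=params,
                      protocol_name=protocol.name)
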
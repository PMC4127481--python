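"""Named in-silico experiment protocols.

Each scenario encodes one of the published perturbation experiments:
osmotic up/down shifts with their prescribed radius ramps, media Ca2+ and
pH steps, the Raba4d fusion-rate knockdown, equilibrium wall-viscosity
ramps, oil-injection changes of the cellular osmolyte pool, and constant
sweep conditions used for steady-state comparisons.
"""

from __future__ import annotations

import numpy as np

from .parameters import Parameters
from .protocol import (ScenarioProtocol, PiecewiseLinear, constant_protocol,
                       step_course, ramp_course)

SCENARIO_NAMES = [
    "isotonic", "hypotonic_018", "hypertonic_116", "calcium_shift",
    "ph_shift", "raba4d", "viscosity_ramp", "oil_injection",
    "osmolarity_sweep", "viscosity_sweep",
]

# default media composition (M); the non-ionic osmolyte tops the total up
_MEDIA = {"Ca_o": 1.0e-3, "H_o": 10 ** -5.7, "K_o": 1.0e-3, "Cl_o": 1.0e-3}
_T_SHIFT = 7200.0
_STEP_W = 1.0


def _base_courses(total_osm: float, eta_eq: float, Osm_i: float,
                  fusion: float, r: float) -> dict:
    ions = sum(_MEDIA.values())
    mk = PiecewiseLinear.constant
    return {
        "Ca_o": mk(_MEDIA["Ca_o"]), "H_o": mk(_MEDIA["H_o"]),
        "K_o": mk(_MEDIA["K_o"]), "Cl_o": mk(_MEDIA["Cl_o"]),
        "Osm_o": mk(total_osm - ions), "eta_eq": mk(eta_eq),
        "Osm_i": mk(Osm_i), "fusion_scale": mk(fusion), "r": mk(r),
    }


def build_scenario(name: str, params: Parameters | None = None,
                   overrides: dict | None = None
                   ) -> tuple[Parameters, ScenarioProtocol]:
    """Return ``(params, protocol)`` for a named scenario.

    ``overrides`` may adjust scenario knobs: ``total_osm`` / ``eta_eq``
    (sweep scenarios), ``t_shift`` and protocol-wide constants.
    """
    from .config import default_parameters  # shipped calibrated set
    ov = dict(overrides or {})
    params = (params or default_parameters()).copy()
    t_shift = float(ov.pop("t_shift", _T_SHIFT))
    ions = sum(_MEDIA.values())
    base_eta = params.eta_eq
    base_osm_i = params.Osm_i

    if name == "isotonic":
        proto = constant_protocol(total_osm=0.36, eta_eq=base_eta,
                                  Osm_i=base_osm_i, r=params.r0,
                                  name=name, **_MEDIA)
    elif name == "hypotonic_018":
        # default: step change with the prescribed 5 -> 5.5 um radius ramp;
        # overrides ramp_width=1000, radius_ramp=False give the slow-ramp,
        # fixed-radius variant used for the turgor/extensibility readouts
        width = float(ov.pop("ramp_width", _STEP_W))
        radius_ramp = bool(ov.pop("radius_ramp", True))
        courses = _base_courses(0.36, base_eta, base_osm_i, 1.0, params.r0)
        courses["Osm_o"] = step_course(0.36 - ions, 0.18 - ions, t_shift,
                                       width)
        if radius_ramp:
            courses["r"] = ramp_course(5.0e-6, 5.5e-6, t_shift,
                                       t_shift + 1800.0)
        proto = ScenarioProtocol(courses=courses, name=name)
    elif name == "hypertonic_116":
        courses = _base_courses(0.36, base_eta, base_osm_i, 1.0, params.r0)
        courses["Osm_o"] = step_course(0.36 - ions, 1.16 - ions, t_shift,
                                       _STEP_W)
        courses["r"] = ramp_course(5.0e-6, 3.5e-6, t_shift, t_shift + 1800.0)
        proto = ScenarioProtocol(courses=courses, name=name)
    elif name == "calcium_shift":
        t2 = float(ov.pop("t_back", t_shift + 3600.0))
        courses = _base_courses(0.36, base_eta, base_osm_i, 1.0, params.r0)
        courses["Ca_o"] = step_course(0.13e-3, 1.3e-3, t_shift, _STEP_W, t2)
        courses["Osm_o"] = PiecewiseLinear.constant(
            0.36 - (0.13e-3 + _MEDIA["H_o"] + _MEDIA["K_o"]
                    + _MEDIA["Cl_o"]))
        proto = ScenarioProtocol(courses=courses, name=name)
    elif name == "ph_shift":
        t2 = float(ov.pop("t_back", t_shift + 3600.0))
        courses = _base_courses(0.36, base_eta, base_osm_i, 1.0, params.r0)
        courses["H_o"] = step_course(10 ** -5.7, 10 ** -5.1, t_shift,
                                     _STEP_W, t2)
        proto = ScenarioProtocol(courses=courses, name=name)
    elif name == "raba4d":
        # fusion-rate parameter 21.5 -> 0.215 um^3/(mM s); mutant radius 12 um
        r = float(ov.pop("r", 12.0e-6))
        scale = float(ov.pop("fusion_scale", 0.01))
        proto = constant_protocol(total_osm=0.36, eta_eq=base_eta,
                                  Osm_i=base_osm_i, fusion_scale=scale,
                                  r=r, name=name, **_MEDIA)
    elif name == "viscosity_ramp":
        # 25 | ramp 25->125 | 125 | ramp 125->225 | 225 MPa s
        t1, t2, t3, t4 = 6000.0, 8000.0, 10000.0, 12000.0
        courses = _base_courses(0.18, base_eta, base_osm_i, 1.0, params.r0)
        courses["eta_eq"] = PiecewiseLinear(
            np.array([0.0, t1, t2, t3, t4]),
            np.array([25e6, 25e6, 125e6, 125e6, 225e6]))
        proto = ScenarioProtocol(courses=courses, name=name)
    elif name == "oil_injection":
        # cellular osmolyte pool ramped 0.5->0.75 M then reset, then 0.5->1.0;
        # the pool is directly controlled here (injection, not supply)
        params = params.copy(osmolyte_dynamic=False)
        t1 = t_shift
        t2, t3, t4 = t1 + 1000.0, t1 + 3600.0, t1 + 4600.0
        courses = _base_courses(0.36, base_eta, 0.5, 1.0, params.r0)
        courses["Osm_i"] = PiecewiseLinear(
            np.array([0.0, t1, t2, t2 + _STEP_W, t3, t4, t4 + _STEP_W]),
            np.array([0.5, 0.5, 0.75, 0.5, 0.5, 1.0, 0.5]))
        proto = ScenarioProtocol(courses=courses, name=name)
    elif name == "osmolarity_sweep":
        total = float(ov.pop("total_osm", 0.36))
        eta = float(ov.pop("eta_eq", base_eta))
        proto = constant_protocol(total_osm=total, eta_eq=eta,
                                  Osm_i=base_osm_i, r=params.r0,
                                  name=f"{name}_{total:g}", **_MEDIA)
        params = params.copy(eta_eq=eta)
    elif name == "viscosity_sweep":
        eta = float(ov.pop("eta_eq", 125e6))
        total = float(ov.pop("total_osm", 0.18))
        proto = constant_protocol(total_osm=total, eta_eq=eta,
                                  Osm_i=base_osm_i, r=params.r0,
                                  name=f"{name}_{eta / 1e6:g}", **_MEDIA)
        params = params.copy(eta_eq=eta)
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}")
    if ov:
        raise ValueError(f"unused scenario overrides: {sorted(ov)}")
    return params, proto
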
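"""Configuration loading/saving (YAML dialect).

A config file has sections ``constants``, ``parameters``, ``protocol``,
``solver`` and ``analysis``; all are optional and unspecified fields take
the documented defaults.  Two unit modes exist:

* ``units: display`` (default for hand-written files): pressures in MPa,
  viscosities in MPa s, lengths in um, areas in um^2, volumes in um^3,
  Lp in m s^-1 MPa^-1, ka in MPa^-1, ion set-points in mM, osmolyte pools
  in Osm (= M of osmotically active solute).
* ``units: si``: values stored as-is (used by :func:`save_config` so that a
  write/read round-trip is bit-identical).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import yaml

from .constants import PhysicalConstants
from .parameters import Parameters
from .protocol import ScenarioProtocol, PiecewiseLinear
from .simulator import SolverSettings
from .oscillations import OscillationSettings


class ConfigError(ValueError):
    pass


# display-unit -> SI multiplicative factors for Parameters fields
_PARAM_FACTORS = {
    "Lp": 1e-6, "A_osm": 1e-12, "eps": 1e6, "Pc": 1e6, "v_ext": 1e-18,
    "eta_eq": 1e6, "ka": 1e-6, "r0": 1e-6, "ri0": 1e-6, "L0": 1e-6,
    "h0": 1e-6, "setpoint_Ca": 1e-3, "setpoint_H": 1e-3, "setpoint_K": 1e-3,
    "setpoint_Cl": 1e-3,
}
# display-unit factors for protocol courses
_COURSE_FACTORS = {
    "Ca_o": 1e-3, "H_o": 1e-3, "K_o": 1e-3, "Cl_o": 1e-3,  # mM
    "Osm_o": 1.0, "Osm_i": 1.0,                            # Osm
    "eta_eq": 1e6,                                         # MPa s
    "fusion_scale": 1.0, "r": 1e-6,                        # um
}


@dataclass
class Config:
    constants: PhysicalConstants
    parameters: Parameters
    protocol: ScenarioProtocol
    solver: SolverSettings
    analysis: OscillationSettings
    t_span: tuple[float, float] | None = None
    initial_overrides: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.constants, self.parameters, self.protocol,
                     self.solver))


def default_parameters() -> Parameters:
    """The shipped calibrated parameter set."""
    ref = importlib.resources.files("tipgrow.data") / "default_params.yaml"
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return _parse_parameters(doc.get("parameters", {}),
                             display=doc.get("units", "si") != "si")


def _parse_parameters(section: dict, display: bool) -> Parameters:
    base = Parameters()
    values: dict = {}
    for key, val in section.items():
        if not hasattr(base, key):
            raise ConfigError(f"unknown parameter field {key!r}")
        if isinstance(val, dict):
            values[key] = val
        elif isinstance(val, bool):
            values[key] = val
        else:
            if isinstance(val, str):
                try:
                    val = float(val)  # YAML 1.1 floats like "2.5e7"
                except ValueError:
                    raise ConfigError(
                        f"parameter {key!r} is not numeric: {val!r}")
            f = _PARAM_FACTORS.get(key, 1.0) if display else 1.0
            values[key] = float(val) * f
    merged = base.to_dict()
    merged.update(values)
    try:
        return Parameters.from_dict(merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _parse_course(key: str, val, display: bool) -> PiecewiseLinear:
    f = _COURSE_FACTORS.get(key, 1.0) if display else 1.0
    if isinstance(val, (int, float)):
        return PiecewiseLinear.constant(float(val) * f)
    if isinstance(val, dict) and "times" in val and "values" in val:
        import numpy as np
        return PiecewiseLinear(np.asarray(val["times"], float),
                               np.asarray(val["values"], float) * f)
    raise ConfigError(f"course {key!r} must be a number or "
                      "{times: [...], values: [...]}")


def _parse_protocol(section: dict, params: Parameters,
                    display: bool) -> ScenarioProtocol:
    from .scenarios import build_scenario
    section = dict(section)
    scenario = section.pop("scenario", None)
    course_spec = section.pop("courses", {})
    overrides = section.pop("overrides", {})
    if section:
        raise ConfigError(f"unknown protocol keys: {sorted(section)}")
    if scenario is not None:
        _, proto = build_scenario(scenario, params=params,
                                  overrides=overrides)
    else:
        from .protocol import constant_protocol
        proto = constant_protocol(total_osm=0.36, eta_eq=params.eta_eq,
                                  Osm_i=params.Osm_i, r=params.r0)
    if course_spec:
        courses = dict(proto.courses)
        for key, val in course_spec.items():
            if key not in courses:
                raise ConfigError(f"unknown protocol course {key!r}")
            courses[key] = _parse_course(key, val, display)
        proto = ScenarioProtocol(courses=courses, name=proto.name)
    return proto


def load_config(path) -> Config:
    """Load and validate a config file.

    Raises :class:`ConfigError` naming the offending field on missing or
    invalid entries.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    display = doc.get("units", "display") != "si"
    known = {"units", "constants", "parameters", "protocol", "solver",
             "analysis", "initial_state"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    cdict = doc.get("constants", {}) or {}
    try:
        constants = PhysicalConstants(**cdict)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"constants: {exc}") from exc

    params = _parse_parameters(doc.get("parameters", {}) or {}, display)
    protocol = _parse_protocol(doc.get("protocol", {}) or {}, params, display)

    sdict = dict(doc.get("solver", {}) or {})
    t_span = sdict.pop("t_span", None)
    if t_span is not None:
        t_span = (float(t_span[0]), float(t_span[1]))
    try:
        solver = SolverSettings(**sdict)
    except TypeError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    adict = doc.get("analysis", {}) or {}
    try:
        analysis = OscillationSettings(**adict)
    except TypeError as exc:
        raise ConfigError(f"analysis: {exc}") from exc

    init = dict(doc.get("initial_state", {}) or {})
    return Config(constants=constants, parameters=params, protocol=protocol,
                  solver=solver, analysis=analysis, t_span=t_span,
                  initial_overrides=init)


def save_config(path, parameters: Parameters,
                constants: PhysicalConstants | None = None,
                protocol_courses: dict | None = None,
                solver: SolverSettings | None = None) -> None:
    """Write a config in SI mode (round-trips bit-identically)."""
    doc: dict = {"units": "si", "parameters": parameters.to_dict()}
    if constants is not None:
        doc["constants"] = {"R": constants.R, "T": constants.T,
                            "F": constants.F}
    if protocol_courses is not None:
        doc["protocol"] = {"courses": {
            k: {"times": c.times.tolist(), "values": c.values.tolist()}
            for k, c in protocol_courses.items()}}
    if solver is not None:
        sd = asdict(solver)
        doc["solver"] = sd
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
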
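"""Time-dependent scenario protocols.

Every externally controlled quantity (media composition, equilibrium wall
viscosity, cellular non-ionic osmolyte pool, fusion-rate scale and the
prescribed outer radius) is a piecewise-linear function of time.  Step
changes are encoded as short ramps (default 1 s wide) so the ODE right-hand
side stays solver-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ProtocolRangeError(ValueError):
    """Time outside of the protocol's span."""


@dataclass
class PiecewiseLinear:
    """Piecewise-linear course defined by strictly increasing breakpoints."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size == 0:
            raise ValueError("empty time course")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, value: float, t0: float = 0.0,
                 t1: float = np.inf) -> "PiecewiseLinear":
        if np.isinf(t1):
            return cls(np.array([t0]), np.array([float(value)]))
        return cls(np.array([t0, t1]), np.array([float(value)] * 2))

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        """Courses hold their final value indefinitely (step-and-hold)."""
        return np.inf

    @property
    def t_last(self) -> float:
        return float(self.times[-1])

    def __call__(self, t: float) -> float:
        if t < self.t_start - 1e-9:
            raise ProtocolRangeError(
                f"t={t} before course start {self.t_start}")
        if self.times.size == 1 or t >= self.t_last:
            return float(self.values[-1])
        return float(np.interp(t, self.times, self.values))

    def slope(self, t: float) -> float:
        """Slope of the active segment (0 for constant/held courses).

        At exactly the final breakpoint the last segment's slope is
        reported (the ramp is considered to include its endpoint).
        """
        if t < self.t_start - 1e-9:
            raise ProtocolRangeError(
                f"t={t} before course start {self.t_start}")
        if self.times.size == 1 or t > self.t_last:
            return 0.0
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        i = min(max(i, 0), self.times.size - 2)
        dt = self.times[i + 1] - self.times[i]
        return float((self.values[i + 1] - self.values[i]) / dt)


@dataclass(frozen=True)
class ExternalConditions:
    """All externally controlled quantities evaluated at one time (SI)."""

    Ca_o: float    # M
    H_o: float     # M
    K_o: float     # M
    Cl_o: float    # M
    Osm_o: float   # M, non-ionic media osmolyte
    eta_eq: float  # Pa s
    Osm_i: float   # M, cellular non-ionic osmolyte pool
    fusion_scale: float
    r: float       # m
    dr_dt: float   # m s^-1


#: course name -> positivity required
_COURSES = {
    "Ca_o": True, "H_o": True, "K_o": True, "Cl_o": True, "Osm_o": True,
    "eta_eq": True, "Osm_i": True, "fusion_scale": True, "r": True,
}


@dataclass
class ScenarioProtocol:
    """Bundle of piecewise-linear courses for one in-silico experiment."""

    courses: dict = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        for key in _COURSES:
            if key not in self.courses:
                raise ValueError(f"protocol missing course {key!r}")
        for key, course in self.courses.items():
            if np.any(course.values < 0):
                raise ValueError(f"course {key!r} has negative values")
        if np.any(self.courses["r"].values <= 0):
            raise ValueError("radius course must be strictly positive")

    @property
    def t_span(self) -> tuple[float, float]:
        t0 = max(c.t_start for c in self.courses.values())
        t1 = min(c.t_end for c in self.courses.values())
        return (t0, t1)

    def breakpoints(self) -> np.ndarray:
        pts = np.concatenate([c.times for c in self.courses.values()])
        return np.unique(pts[np.isfinite(pts)])

    def at(self, t: float) -> ExternalConditions:
        c = self.courses
        return ExternalConditions(
            Ca_o=c["Ca_o"](t), H_o=c["H_o"](t), K_o=c["K_o"](t),
            Cl_o=c["Cl_o"](t), Osm_o=c["Osm_o"](t), eta_eq=c["eta_eq"](t),
            Osm_i=c["Osm_i"](t), fusion_scale=c["fusion_scale"](t),
            r=c["r"](t), dr_dt=c["r"].slope(t),
        )


def protocol_at(protocol: ScenarioProtocol, t: float) -> ExternalConditions:
    """Evaluate every controlled quantity (and dr/dt) at time ``t``."""
    return protocol.at(t)


def constant_protocol(*, Ca_o: float = 1.0e-3, H_o: float = 10 ** -5.7,
                      K_o: float = 1.0e-3, Cl_o: float = 1.0e-3,
                      Osm_o: float | None = None, total_osm: float = 0.36,
                      eta_eq: float = 25.0e6, Osm_i: float = 0.5,
                      fusion_scale: float = 1.0, r: float = 5.0e-6,
                      name: str = "constant") -> ScenarioProtocol:
    """Constant-conditions protocol.

    If ``Osm_o`` is not given it is chosen so that the *total* media
    osmolarity (ions + other solutes) equals ``total_osm``.
    """
    ions = Ca_o + H_o + K_o + Cl_o
    if Osm_o is None:
        Osm_o = total_osm - ions
        if Osm_o < 0:
            raise ValueError("ionic content exceeds requested total osmolarity")
    mk = PiecewiseLinear.constant
    return ScenarioProtocol(courses={
        "Ca_o": mk(Ca_o), "H_o": mk(H_o), "K_o": mk(K_o), "Cl_o": mk(Cl_o),
        "Osm_o": mk(Osm_o), "eta_eq": mk(eta_eq), "Osm_i": mk(Osm_i),
        "fusion_scale": mk(fusion_scale), "r": mk(r),
    }, name=name)


def step_course(baseline: float, value: float, t_step: float,
                width: float = 1.0,
                t_back: float | None = None) -> PiecewiseLinear:
    """Step encoded as a narrow linear ramp (optionally stepping back)."""
    times = [0.0, t_step, t_step + width]
    values = [baseline, baseline, value]
    if t_back is not None:
        times += [t_back, t_back + width]
        values += [value, baseline]
    return PiecewiseLinear(np.array(times), np.array(values))


def ramp_course(baseline: float, value: float, t_start: float,
                t_end: float) -> PiecewiseLinear:
    """Genuine linear ramp from ``baseline`` to ``value``."""
    return PiecewiseLinear(np.array([0.0, t_start, t_end]),
                           np.array([baseline, baseline, value]))
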
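"""Shared fixtures: the calibrated scenario runs used across the suite.

The long scenario integrations are session-scoped so each is computed once.
"""

import numpy as np
import pytest

import tipgrow as tg

#: sampling used by the shared runs (coarser than the CLI default but well
#: above 10 samples per cycle for every scenario)
SETTINGS = tg.SolverSettings(dt_sample=0.25)


def run_scenario(name, t_end, overrides=None, settings=SETTINGS):
    params, protocol = tg.build_scenario(name, overrides=overrides)
    return tg.run_simulation(params, protocol, (0.0, t_end), settings), params


def window(traj, t0, t1):
    m = (traj.t >= t0) & (traj.t <= t1)
    return traj.t[m], traj.data[m]


def measure(traj, t0, t1, var="growth_rate_um_min"):
    """Oscillation summary of ``var`` over [t0, t1]."""
    t, d = window(traj, t0, t1)
    return tg.detect_oscillation(
        t, d[var].to_numpy(),
        settings=tg.OscillationSettings(tail_fraction=1.0))


@pytest.fixture(scope="session")
def default_params():
    return tg.default_parameters()


@pytest.fixture(scope="session")
def iso_run():
    """Isotonic 0.36 Osm, 7200 s (the reference limit cycle)."""
    traj, params = run_scenario("isotonic", 7200.0)
    return traj


@pytest.fixture(scope="session")
def hypo_const_run():
    """Constant 0.18 Osm limit cycle (regulation comparison partner)."""
    traj, params = run_scenario("osmolarity_sweep", 7200.0,
                                {"total_osm": 0.18})
    return traj


@pytest.fixture(scope="session")
def hypo_shift_run():
    """0.36 -> 0.18 Osm step at 7200 s with the 5 -> 5.5 um radius ramp."""
    traj, params = run_scenario("hypotonic_018", 10800.0)
    return traj


@pytest.fixture(scope="session")
def hyper_run():
    """0.36 -> 1.16 Osm step at 7200 s with the 5 -> 3.5 um radius ramp."""
    traj, params = run_scenario("hypertonic_116", 15000.0)
    return traj


@pytest.fixture(scope="session")
def fig6_run():
    """Slow 1000 s osmolarity ramp 0.36 -> 0.18, fixed radius."""
    traj, params = run_scenario("hypotonic_018", 10800.0,
                                {"ramp_width": 1000.0, "radius_ramp": False})
    return traj


@pytest.fixture(scope="session")
def viscosity_pair():
    """Limit cycles at equilibrium wall viscosity 125 and 225 MPa s."""
    tra, pa = run_scenario("viscosity_sweep", 7200.0, {"eta_eq": 125e6})
    trb, pb = run_scenario("viscosity_sweep", 7200.0, {"eta_eq": 225e6})
    return tra, trb, pa
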
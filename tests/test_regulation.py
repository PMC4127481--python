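"""Regulation coefficients on closed-form synthetic oscillatory states."""

import numpy as np
import pandas as pd
import pytest

from tipgrow.parameters import Parameters
from tipgrow.simulator import Trajectory
from tipgrow.regulation import (water_regulation_coefficients,
                                wall_regulation_coefficients,
                                DegenerateComparisonError, LogDomainError)

PAR = Parameters(Lp=1e-12, A_osm=1e-11, v_ext=5e-15, Pc=0.2e6, eps=1e6)
LPA = PAR.Lp * PAR.A_osm
T_CYCLE = 50.0
WINDOW = (100.0, 150.0)


def water_traj(pi_i0, pi_o, P0, pi_amp=0.0, P_amp=0.0):
    """Synthetic state obeying dv/dt = Lp A (pi_i - pi_o - P) pointwise."""
    t = np.arange(0.0, 300.0, 0.02)
    w = 2 * np.pi / T_CYCLE
    pi_i = pi_i0 + pi_amp * np.sin(w * t)
    P = P0 + P_amp * np.sin(w * t + 0.7)
    net = LPA * (pi_i - pi_o - P)
    df = pd.DataFrame({"t": t, "net_water": net, "pi_i": pi_i,
                       "pi_o": np.full_like(t, pi_o), "P": P})
    return Trajectory(t=t, data=df, params=PAR)


def wall_traj(phi0, P0, phi_amp=0.0, P_amp=0.0, v=1e-14):
    """Synthetic state obeying the chamber decomposition pointwise."""
    t = np.arange(0.0, 300.0, 0.02)
    w = 2 * np.pi / T_CYCLE
    phi = phi0 + phi_amp * np.sin(w * t)
    P = P0 + P_amp * np.sin(w * t + 0.3)
    dP_dt = P_amp * w * np.cos(w * t + 0.3)
    plastic_rel = PAR.v_ext / v * phi * (P - PAR.Pc)
    net = v * plastic_rel + v / PAR.eps * dP_dt
    df = pd.DataFrame({"t": t, "net_water": net, "P": P, "phi": phi,
                       "v": np.full_like(t, v), "dP_dt": dP_dt})
    return Trajectory(t=t, data=df, params=PAR)


class TestWaterSide:
    def test_only_media_osmolarity_differs(self):
        o1 = water_traj(1.4e6, 0.9e6, 0.21e6, pi_amp=2e3, P_amp=100.0)
        o2 = water_traj(1.4e6, 0.5e6, 0.21e6, pi_amp=2e3, P_amp=100.0)
        rep = water_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)
        assert rep.R_pi_o_w == pytest.approx(1.0, abs=1e-9)
        assert rep.R_pi_i_w == pytest.approx(0.0, abs=1e-9)
        assert rep.R_P_w == pytest.approx(0.0, abs=1e-9)

    def test_general_pair_against_hand_computed(self):
        o1 = water_traj(1.40e6, 0.90e6, 0.214e6, pi_amp=3e3, P_amp=250.0)
        o2 = water_traj(1.41e6, 0.45e6, 0.229e6, pi_amp=1e3, P_amp=90.0)
        rep = water_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)

        def avg(traj, col):
            m = (traj.t >= WINDOW[0]) & (traj.t <= WINDOW[1])
            return np.trapezoid(traj.data[col][m], traj.t[m]) / (
                WINDOW[1] - WINDOW[0])

        den = avg(o1, "net_water") - avg(o2, "net_water")
        exp_pi_i = LPA * (avg(o1, "pi_i") - avg(o2, "pi_i")) / den
        exp_pi_o = -LPA * (avg(o1, "pi_o") - avg(o2, "pi_o")) / den
        exp_P = -LPA * (avg(o1, "P") - avg(o2, "P")) / den
        assert rep.R_pi_i_w == pytest.approx(exp_pi_i, abs=1e-9)
        assert rep.R_pi_o_w == pytest.approx(exp_pi_o, abs=1e-9)
        assert rep.R_P_w == pytest.approx(exp_P, abs=1e-9)

    def test_sum_is_one(self):
        o1 = water_traj(1.40e6, 0.90e6, 0.214e6, pi_amp=3e3, P_amp=250.0)
        o2 = water_traj(1.39e6, 0.45e6, 0.229e6)
        rep = water_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)
        assert rep.water_sum == pytest.approx(1.0, abs=1e-12)

    def test_swap_invariance(self):
        o1 = water_traj(1.40e6, 0.90e6, 0.214e6, pi_amp=3e3)
        o2 = water_traj(1.42e6, 0.45e6, 0.229e6, P_amp=120.0)
        a = water_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)
        b = water_regulation_coefficients(o2, o1, PAR, WINDOW, WINDOW)
        assert a.R_pi_i_w == pytest.approx(b.R_pi_i_w, rel=1e-12)
        assert a.R_pi_o_w == pytest.approx(b.R_pi_o_w, rel=1e-12)
        assert a.R_P_w == pytest.approx(b.R_P_w, rel=1e-12)

    def test_identical_states_degenerate(self):
        o1 = water_traj(1.40e6, 0.90e6, 0.214e6, pi_amp=3e3)
        with pytest.raises(DegenerateComparisonError):
            water_regulation_coefficients(o1, o1, PAR, WINDOW, WINDOW)


class TestWallSide:
    def test_only_extensibility_differs(self):
        o1 = wall_traj(4.5e-8, 0.25e6)
        o2 = wall_traj(6.0e-8, 0.25e6)
        rep = wall_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)
        assert rep.R_phi_c == pytest.approx(1.0, abs=1e-9)
        assert rep.R_P_c == pytest.approx(0.0, abs=1e-9)
        assert rep.R_O_c == pytest.approx(0.0, abs=1e-9)

    def test_elastic_term_zero_for_steady_turgor(self):
        o1 = wall_traj(4.5e-8, 0.25e6, phi_amp=2e-9)
        o2 = wall_traj(5.5e-8, 0.27e6, phi_amp=1e-9)
        rep = wall_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)
        assert rep.R_O_c == pytest.approx(0.0, abs=1e-9)
        assert rep.wall_sum == pytest.approx(1.0, abs=1e-9)

    def test_sum_is_one_with_elastic_correction(self):
        o1 = wall_traj(4.5e-8, 0.25e6, phi_amp=2e-9, P_amp=300.0)
        o2 = wall_traj(5.5e-8, 0.28e6, phi_amp=1e-9, P_amp=150.0)
        rep = wall_regulation_coefficients(o1, o2, PAR, WINDOW, WINDOW)
        assert rep.wall_sum == pytest.approx(1.0, abs=1e-6)

    def test_turgor_below_critical_rejected(self):
        o1 = wall_traj(4.5e-8, 0.25e6)
        bad = wall_traj(4.5e-8, 0.15e6)  # P < Pc
        with pytest.raises(LogDomainError):
            wall_regulation_coefficients(o1, bad, PAR, WINDOW, WINDOW)


def test_model_pair_sums(iso_run, hypo_const_run):
    """On real model output the water sum is 1 within 1e-6 and the wall
    sum within 1e-3."""
    from tipgrow.regulation import regulation_report
    rep = regulation_report(iso_run, hypo_const_run, iso_run.params)
    assert rep.water_sum == pytest.approx(1.0, abs=1e-6)
    assert rep.wall_sum == pytest.approx(1.0, abs=1e-3)


def test_limit_cycle_stationarity(iso_run):
    """Consecutive exact-period averages of a converged cycle agree to
    0.1% (the convergence criterion for regulation windows)."""
    from tipgrow.regulation import stationarity
    assert stationarity(iso_run) < 1e-3


def test_multi_period_averaging_agrees(iso_run, hypo_const_run):
    """Two-period averaging changes the coefficients by < 0.5%."""
    from tipgrow.regulation import regulation_report
    one = regulation_report(iso_run, hypo_const_run, iso_run.params)
    two = regulation_report(iso_run, hypo_const_run, iso_run.params,
                            n_periods=2)
    for attr in ("R_pi_o_w", "R_P_w", "R_phi_c", "R_P_c"):
        a, b = getattr(one, attr), getattr(two, attr)
        assert abs(a - b) <= 0.005 * max(abs(a), 1.0)
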
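"""Osmotic water flow, Lockhart extension and the turgor balance."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import linregress

import tipgrow.hydrodynamics as hd
from tipgrow.constants import DEFAULT_CONSTANTS as C

R, T = C.R, C.T


class TestOsmoticPressure:
    def test_zero(self):
        assert hd.osmotic_pressure(0, 0, 0, 0, 0, R, T) == 0.0

    def test_total_036_osm(self):
        # 0.36 Osm total at 298.15 K -> ~8.92e5 Pa
        pi = hd.osmotic_pressure(0, 0, 0, 0, 0.36, R, T)
        assert pi == pytest.approx(R * T * 360.0, rel=1e-12)
        assert pi == pytest.approx(8.92e5, rel=1e-2)

    def test_redistribution_invariance(self):
        a = hd.osmotic_pressure(0.1, 0.0, 0.2, 0.05, 0.01, R, T)
        b = hd.osmotic_pressure(0.0, 0.36, 0.0, 0.0, 0.0, R, T)
        assert a == pytest.approx(b, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hd.osmotic_pressure(-0.1, 0, 0, 0, 0.3, R, T)


class TestWaterRate:
    def test_osmotic_equilibrium(self):
        _, _, net = hd.water_volume_rate(1e-14, 1e5, 9e5, 8e5, 1e-12, 1e-11)
        assert net == pytest.approx(0.0, abs=1e-30)

    def test_direct_arithmetic(self):
        infl, outfl, net = hd.water_volume_rate(
            1e-14, 0.2e6, 1.2e6, 0.9e6, 1e-12, 1e-11)
        assert infl == pytest.approx(1e-23 * 0.3e6)
        assert outfl == pytest.approx(1e-23 * 0.2e6)
        assert net == infl - outfl

    def test_exponential_growth_when_area_scales_with_volume(self):
        """If the water-permeable area grows with the cell volume the tube
        grows exponentially (log-linear R^2 > 0.9999)."""
        alpha = 1e-11 / 1e-14  # area per volume
        dpi_minus_P = 1e5

        def rhs(t, y):
            _, _, net = hd.water_volume_rate(y[0], 0.0, dpi_minus_P, 0.0,
                                             1e-12, alpha * y[0])
            return [net]

        rate = 1e-12 * alpha * dpi_minus_P
        t_end = 10 * math.log(2) / rate
        sol = solve_ivp(rhs, (0, t_end), [1e-14], rtol=1e-10, atol=1e-20,
                        t_eval=np.linspace(0, t_end, 200))
        fit = linregress(sol.t, np.log(sol.y[0]))
        assert fit.rvalue ** 2 > 0.9999
        assert fit.slope == pytest.approx(rate, rel=1e-6)


class TestChamberRate:
    def test_rest(self):
        assert hd.wall_chamber_rate(1e-14, 1e-15, 4e-8, 0.2e6, 0.2e6,
                                    1e6, 0.0) == 0.0

    def test_uniform_extensibility_lockhart_exponential(self):
        """With v_ext = v (wall yields everywhere) and constant turgor the
        chamber volume grows exponentially."""
        phi, P, Pc = 4e-8, 0.25e6, 0.2e6

        def rhs(t, y):
            return [hd.wall_chamber_rate(y[0], y[0], phi, P, Pc, 1e6, 0.0)]

        rate = phi * (P - Pc)
        t_end = 10 * math.log(2) / rate
        sol = solve_ivp(rhs, (0, t_end), [1e-14], rtol=1e-10, atol=1e-20,
                        t_eval=np.linspace(0, t_end, 200))
        fit = linregress(sol.t, np.log(sol.y[0]))
        assert fit.rvalue ** 2 > 0.9999
        assert fit.slope == pytest.approx(rate, rel=1e-6)

    def test_plastic_term_linear_in_vext(self):
        a = hd.wall_chamber_rate(1e-14, 1e-15, 4e-8, 0.3e6, 0.2e6, 1e6, 0.0)
        b = hd.wall_chamber_rate(1e-14, 2e-15, 4e-8, 0.3e6, 0.2e6, 1e6, 0.0)
        assert b == pytest.approx(2 * a)

    def test_no_plastic_flow_below_critical_turgor(self):
        assert hd.wall_chamber_rate(1e-14, 1e-15, 4e-8, 0.1e6, 0.2e6,
                                    1e6, 0.0) == 0.0


class TestTurgor:
    ARGS = dict(pi_i=1.4e6, pi_o=0.9e6, phi=4.5e-8, Lp=1e-12,
                A_osm=1.1e-11, v_ext=5e-15, Pc=0.199e6)

    def test_fixed_point_formula(self):
        P_ss = hd.turgor_fixed_point(**self.ARGS)
        rhs = hd.turgor_rhs(1e-14, P_ss, self.ARGS["pi_i"],
                            self.ARGS["pi_o"], self.ARGS["phi"],
                            self.ARGS["Lp"], self.ARGS["A_osm"],
                            self.ARGS["v_ext"], self.ARGS["Pc"], eps=1e6)
        assert rhs == pytest.approx(0.0, abs=1e-8)

    def test_simulated_convergence_to_fixed_point(self):
        P_ss = hd.turgor_fixed_point(**self.ARGS)
        a = self.ARGS

        def rhs(t, y):
            return [hd.turgor_rhs(1e-14, y[0], a["pi_i"], a["pi_o"],
                                  a["phi"], a["Lp"], a["A_osm"], a["v_ext"],
                                  a["Pc"], eps=1e6)]

        sol = solve_ivp(rhs, (0, 5000), [0.15e6], rtol=1e-10, atol=1.0)
        assert sol.y[0, -1] == pytest.approx(P_ss, rel=1e-6)

    def test_eps_linearity(self):
        a = self.ARGS
        r1 = hd.turgor_rhs(1e-14, 0.25e6, a["pi_i"], a["pi_o"], a["phi"],
                           a["Lp"], a["A_osm"], a["v_ext"], a["Pc"], eps=1e6)
        r2 = hd.turgor_rhs(1e-14, 0.25e6, a["pi_i"], a["pi_o"], a["phi"],
                           a["Lp"], a["A_osm"], a["v_ext"], a["Pc"], eps=2e6)
        assert r2 == pytest.approx(2 * r1)

    def test_fixed_point_monotone_in_dpi_and_viscosity(self):
        base = hd.turgor_fixed_point(**self.ARGS)
        richer = hd.turgor_fixed_point(**{**self.ARGS, "pi_i": 1.6e6})
        stiffer = hd.turgor_fixed_point(**{**self.ARGS, "phi": 2e-8})
        assert richer > base          # more osmotic drive -> more turgor
        assert stiffer > base         # lower extensibility -> more turgor

    def test_two_opposing_roles_of_turgor(self):
        a = self.ARGS
        dP = 1e3
        w_lo = hd.water_volume_rate(1e-14, 0.25e6, a["pi_i"], a["pi_o"],
                                    a["Lp"], a["A_osm"])[2]
        w_hi = hd.water_volume_rate(1e-14, 0.25e6 + dP, a["pi_i"], a["pi_o"],
                                    a["Lp"], a["A_osm"])[2]
        c_lo = hd.wall_chamber_rate(1e-14, a["v_ext"], a["phi"], 0.25e6,
                                    a["Pc"], 1e6, 0.0)
        c_hi = hd.wall_chamber_rate(1e-14, a["v_ext"], a["phi"], 0.25e6 + dP,
                                    a["Pc"], 1e6, 0.0)
        assert w_hi < w_lo            # turgor pushes water out
        assert c_hi > c_lo            # turgor extends the wall


class TestGrowthRateConversion:
    def test_fixed_radius(self):
        # dv/dt = 3.45 um^3/s at r = 5 um -> ~0.0439 um/s (2.64 um/min)
        dLdt = hd.growth_rate_from_volume(3.45e-18, 5e-6, 0.0, 5e-4)
        assert dLdt == pytest.approx(3.45e-18 / (math.pi * 25e-12), rel=1e-12)
        assert dLdt * 6e7 == pytest.approx(2.64, rel=5e-3)

    def test_pure_radial_swelling(self):
        r, L, drdt = 5e-6, 5e-4, 1e-10
        dvdt = 2 * math.pi * r * L * drdt
        assert hd.growth_rate_from_volume(dvdt, r, drdt, L) == pytest.approx(
            0.0, abs=1e-30)

    def test_volume_roundtrip_consistency(self):
        """v(t) rebuilt from integrated dL/dt and r(t) matches integrated
        dv/dt."""
        r0, drdt, L0 = 5e-6, 2.78e-10, 4e-4
        dvdt = 5e-18
        t = np.linspace(0, 1800, 500)
        r = r0 + drdt * t
        # integrate dL/dt with the same dv/dt
        L = np.empty_like(t)
        L[0] = L0
        for i in range(1, len(t)):
            dt = t[i] - t[i - 1]
            dL = hd.growth_rate_from_volume(dvdt, r[i - 1], drdt, L[i - 1])
            Lm = L[i - 1] + 0.5 * dt * dL
            rm = r0 + drdt * (t[i - 1] + 0.5 * dt)
            dL = hd.growth_rate_from_volume(dvdt, rm, drdt, Lm)
            L[i] = L[i - 1] + dt * dL
        v_geo = math.pi * r ** 2 * L
        v_int = math.pi * r0 ** 2 * L0 + dvdt * t
        assert np.allclose(v_geo, v_int, rtol=1e-6)
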
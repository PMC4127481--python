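"""Transporter kernels: ohmic/GHK currents and stretch-channel gating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tipgrow.ion_transport as it
from tipgrow.constants import DEFAULT_CONSTANTS as C
from tipgrow.parameters import Parameters
from tipgrow.ion_dynamics import ion_rhs, IonState
from tipgrow.ion_transport import CurrentSet, GateState

VREF = C.Vref


@pytest.mark.parametrize("g,V,E,expected", [
    (1.0, -0.1, -0.1, 0.0),          # reversal
    (0.0, 0.3, -0.5, 0.0),           # zero conductance
    (2.0, -0.1, -0.15, 0.1),         # direct arithmetic
])
def test_ohmic_current(g, V, E, expected):
    assert it.ohmic_current(g, V, E) == pytest.approx(expected, abs=1e-15)


class TestGHK:
    def test_zero_at_nernst_potential(self):
        for z, ci, ce in [(1, 0.05, 0.001), (2, 1e-5, 1e-3), (-1, 0.01, 0.002)]:
            E = it.nernst_potential(z, ci, ce, VREF)
            assert it.ghk_current(1.0, E, z, ci, ce, VREF) == pytest.approx(
                0.0, abs=1e-12)

    def test_equal_concentrations_collapse_to_gVc(self):
        c = 0.02
        for V in [-0.15, -0.03, 0.01, 0.1]:
            assert it.ghk_current(3.0, V, 1, c, c, VREF) == pytest.approx(
                3.0 * V * c, rel=1e-12)

    def test_small_voltage_series_limit(self):
        # full expression at V = +-1e-9 must match the series limit
        g, z, ci, ce = 2.0, 2, 1e-5, 1e-3
        limit = g * VREF * (ci - ce) / z
        for V in (1e-9, -1e-9):
            full_x = z * V / VREF
            em = math.exp(-full_x)
            full = g * V * (ci - ce * em) / (1.0 - em)
            assert it.ghk_current(g, V, z, ci, ce, VREF) == pytest.approx(
                limit, rel=1e-6)
            assert full == pytest.approx(limit, rel=1e-6)

    def test_continuity_across_series_threshold(self):
        g, z, ci, ce = 1.0, 1, 0.05, 0.001
        V_lo = 0.99e-6 * VREF / z
        V_hi = 1.01e-6 * VREF / z
        lo = it.ghk_current(g, V_lo, z, ci, ce, VREF)
        hi = it.ghk_current(g, V_hi, z, ci, ce, VREF)
        assert lo == pytest.approx(hi, rel=1e-5)

    @given(V=st.floats(-0.3, 0.3), ci=st.floats(1e-7, 0.5),
           ce=st.floats(1e-7, 0.5), z=st.sampled_from([1, 2, -1]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sign_changes_only_at_nernst(self, V, ci, ce, z):
        """Away from the Nernst potential the current carries the sign of
        the electrochemical driving force V - E."""
        E = it.nernst_potential(z, ci, ce, VREF)
        I = it.ghk_current(1.0, V, z, ci, ce, VREF)
        if abs(V - E) > 1e-6:
            assert math.copysign(1.0, I) == math.copysign(1.0, V - E)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            it.ghk_current(1.0, -0.1, 0, 0.1, 0.1, VREF)

    def test_extreme_voltages_finite(self):
        assert np.isfinite(it.ghk_current(1.0, -50.0, 1, 0.05, 0.001, VREF))
        assert np.isfinite(it.ghk_current(1.0, 50.0, 1, 0.05, 0.001, VREF))


class TestStretchGating:
    def test_zero_turgor_rates(self):
        assert it.stretch_gate_rates(0.0, 0.4, 0.02, 1e-5) == (0.4, 0.02)

    def test_pressure_independent_when_ka_zero(self):
        for P in [0.0, 1e5, 5e5]:
            kOC, kCO = it.stretch_gate_rates(P, 0.4, 0.02, 0.0)
            assert (kOC, kCO) == (0.4, 0.02)

    def test_exponential_rate_identity(self):
        ka = 2e-5
        _, k1 = it.stretch_gate_rates(1e5, 0.4, 0.02, ka)
        _, k2 = it.stretch_gate_rates(3e5, 0.4, 0.02, ka)
        assert k2 / k1 == pytest.approx(math.exp(ka * 2e5), rel=1e-12)

    def test_rate_capped_in_deep_saturation(self):
        _, kCO = it.stretch_gate_rates(5e6, 0.4, 1.0, 1e-3)
        assert kCO == it.K_CO_MAX

    def test_gate_rhs_fixed_point(self):
        kOC, kCO = 0.3, 0.7
        p_eq = it.gate_equilibrium(kOC, kCO)
        assert it.gate_rhs(p_eq, kOC, kCO) == pytest.approx(0.0, abs=1e-15)
        assert it.gate_rhs(0.0, 0.0, 0.5) == pytest.approx(0.5)

    def test_equilibrium_open_fraction_increases_with_turgor(self):
        ka, kOC0, kCO0 = 2e-5, 0.4, 0.02
        P = np.linspace(0.0, 0.5e6, 40)
        p_inf = []
        for x in P:
            kOC, kCO = it.stretch_gate_rates(x, kOC0, kCO0, ka)
            p_inf.append(it.gate_equilibrium(kOC, kCO))
        assert np.all(np.diff(p_inf) > 0)
        assert all(0.0 <= p <= 1.0 for p in p_inf)


class TestStretchCurrents:
    def _ions(self):
        return ({"Ca": 1e-5, "H": 1e-7, "K": 0.05, "Cl": 0.012},
                {"Ca": 1e-3, "H": 2e-6, "K": 1e-3, "Cl": 1e-3})

    def test_closed_gates_give_zero(self):
        ii, io = self._ions()
        p = Parameters()
        gates = GateState(0.0, 0.0)
        assert it.stretch_currents(ii, io, -0.1, gates, p, C) == (0, 0, 0)

    def test_zero_at_calcium_nernst(self):
        ii, io = self._ions()
        p = Parameters(g_Ca_sa=5.0)
        E_Ca = it.nernst_potential(2, ii["Ca"], io["Ca"], VREF)
        gates = GateState(0.7, 0.0)
        I1, _, _ = it.stretch_currents(ii, io, E_Ca, gates, p, C)
        assert I1 == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_conductance(self):
        ii, io = self._ions()
        gates = GateState(0.5, 0.5)
        a = it.stretch_currents(ii, io, -0.1, gates,
                                Parameters(g_Ca_sa=2.0, g_K_sa=1.0), C)
        b = it.stretch_currents(ii, io, -0.1, gates,
                                Parameters(g_Ca_sa=4.0, g_K_sa=1.0), C)
        assert b[0] == pytest.approx(2 * a[0], rel=1e-12)
        assert b[1] == pytest.approx(a[1], rel=1e-12)


class TestStretchChlorideVariant:
    def test_off_by_default_and_enabled(self):
        ii = {"Ca": 1e-5, "H": 1e-7, "K": 0.05, "Cl": 0.012}
        io = {"Ca": 1e-3, "H": 2e-6, "K": 1e-3, "Cl": 1e-3}
        gates = GateState(0.5, 0.5)
        off = Parameters(g_Cl_sa=0.3)
        assert it.stretch_currents(ii, io, -0.1, gates, off, C,
                                   p_open_Cl=0.5)[2] == 0.0
        on = Parameters(stretch_cl_enabled=True, g_Cl_sa=0.3)
        assert it.stretch_currents(ii, io, -0.1, gates, on, C,
                                   p_open_Cl=0.5)[2] != 0.0


class TestVoltageGatedSet:
    def test_all_conductances_zero(self):
        p = Parameters()
        for k in (p.vg1, p.vg2, p.vg3, p.vg6):
            k.g = 0.0
        p.pump.imax = 0.0
        p.symporter.g = 0.0
        ii = {"Ca": 1e-5, "H": 1e-7, "K": 0.05, "Cl": 0.012}
        io = {"Ca": 1e-3, "H": 2e-6, "K": 1e-3, "Cl": 1e-3}
        assert it.voltage_gated_currents(ii, io, -0.1, p, C) == (0,) * 6

    def test_symporter_two_to_one_stoichiometry(self):
        """The H+ equation receives twice the symporter current that the
        Cl- equation does, at any state."""
        p = Parameters(k_relax_Ca=0, k_relax_H=0, k_relax_K=0, k_relax_Cl=0,
                       buffer_strength_H=0)
        ions = IonState(1e-5, 1e-7, 0.05, 0.012)
        cur = CurrentSet(I_vg5=-3e-4)
        dCa, dH, dK, dCl = ion_rhs(ions, cur, OV=4e5, F=C.F,
                                   rel_vol_rate=0.0, params=p)
        assert dH == pytest.approx(2 * dCl, rel=1e-12)
        assert dCa == 0.0 and dK == 0.0


class TestMembranePotential:
    def test_zero_currents(self):
        assert it.membrane_potential_rhs(CurrentSet(), 0.01) == 0.0

    def test_capacitance_scaling(self):
        cur = CurrentSet(I_vg1=1e-3)
        assert it.membrane_potential_rhs(cur, 0.02) == pytest.approx(
            0.5 * it.membrane_potential_rhs(cur, 0.01))

    def test_balanced_currents(self):
        cur = CurrentSet(I_vg1=2e-3, I_sa1=-2e-3)
        assert it.membrane_potential_rhs(cur, 0.01) == 0.0
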
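"""Pointwise model functions: indicator, kinetics, fluxes, mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burncontract import model_equations as me
from burncontract import parameters as par


class TestWoundIndicator:
    def test_anchor_values(self):
        c_I, c_II = 3.57, 0.1
        assert me.wound_indicator([c_I, 0.0], c_I, c_II) == pytest.approx(0.5)
        assert me.wound_indicator([c_I - 2 * c_II, 0.0], c_I, c_II) == 0.0
        assert me.wound_indicator([0.0, c_I + c_II], c_I, c_II) == 1.0
        assert me.wound_indicator([0.0, 0.0], c_I, c_II) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r1=st.floats(0, 12), r2=st.floats(0, 12))
    def test_monotone_in_radius(self, r1, r2):
        c_I, c_II = 3.78, 0.1
        w1 = me._indicator_of_radius(min(r1, r2), c_I, c_II)
        w2 = me._indicator_of_radius(max(r1, r2), c_I, c_II)
        assert w1 <= w2 + 1e-15

    def test_continuity_at_branch_points(self):
        c_I, c_II = 3.78, 0.1
        for r0 in (c_I - c_II, c_I + c_II):
            lo = me._indicator_of_radius(r0 - 1e-9, c_I, c_II)
            hi = me._indicator_of_radius(r0 + 1e-9, c_I, c_II)
            assert hi - lo == pytest.approx(0.0, abs=1e-7)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            me.wound_indicator([0.0, 0.0], 0.05, 0.1)


class TestInitialState:
    def test_far_field_is_equilibrium(self, table1):
        N, M, c, rho = me.initial_state(None, table1, radius=11.0)
        assert (N, M, c, rho) == (table1.N_bar, 0.0, 0.0, table1.rho_bar)

    def test_wound_center_levels(self, table1):
        p = par.with_overrides(table1, I_w=0.1)
        N, M, c, rho = me.initial_state(None, p, radius=0.0)
        assert N == pytest.approx(1e3)
        assert c == pytest.approx(p.c_w)
        assert rho == pytest.approx(1e-2)

    def test_myofibroblasts_absent_everywhere(self, table1):
        r = np.linspace(0, 12, 50)
        _, M, _, _ = me.initial_state(None, table1, radius=r)
        assert np.all(np.asarray(M) == 0.0)


class TestKinetics:
    def test_mmp_level(self):
        assert me.mmp_level(5.0, 0.0, 2.0, 1e8) == pytest.approx(10.0)
        assert me.mmp_level(0.0, 1e-8, 2.0, 1e8) == 0.0
        # denominator 1 + 2e8 * 1e-8 = 3
        assert me.mmp_level(1e4, 1e-8, 0.1, 2e8) == pytest.approx(1000.0 / 3.0)

    def test_equilibrium_reactions_vanish(self, table1):
        d = par.derive_consistent_constants(table1)
        R = me.reactions(table1.N_bar, 0.0, 0.0, table1.rho_bar, table1,
                         d.q, d.delta_rho)
        # dimensional rates are O(100)/day here; 1e-9 is machine precision
        assert max(abs(float(r)) for r in R) < 1e-9

    def test_no_cells_no_cell_kinetics(self, table1):
        d = par.derive_consistent_constants(table1)
        R_N, R_M, _, _ = me.reactions(0.0, 0.0, 1e-8, 0.05, table1,
                                      d.q, d.delta_rho)
        assert R_N == 0.0 and R_M == 0.0

    def test_pinned_state_against_independent_evaluation(self):
        """Frozen values from a 40-digit arbitrary-precision evaluation of
        the four kinetic laws at (N, M, c, rho) = (1e4, 0, 1e-8, 0.1)."""
        p = par.DimensionalParameters(delta_M=2e-2, k_rho=1.75e-8)
        d = par.derive_consistent_constants(p)
        R_N, R_M, R_c, R_rho = me.reactions(1e4, 0.0, 1e-8, 0.1, p,
                                            d.q, d.delta_rho)
        assert float(R_N) == pytest.approx(-340.0, rel=1e-12)
        assert float(R_M) == pytest.approx(540.0, rel=1e-12)
        assert float(R_c) == pytest.approx(3.3333333333333333e-10, rel=1e-12)
        assert float(R_rho) == pytest.approx(1.7075757575757576e-3, rel=1e-12)

    def test_negative_state_rejected(self, table1):
        d = par.derive_consistent_constants(table1)
        with pytest.raises(ValueError):
            me.reactions(-1.0, 0.0, 0.0, 0.1, table1, d.q, d.delta_rho)

    def test_crowding_clamped_with_warning(self, table1):
        d = par.derive_consistent_constants(table1)
        with pytest.warns(RuntimeWarning):
            R_N, *_ = me.reactions(2e6, 0.0, 0.0, 0.1, table1,
                                   d.q, d.delta_rho)
        assert np.isfinite(R_N)


class TestFluxes:
    def test_zero_gradients_zero_fluxes(self, table1):
        J = me.fluxes(1e4, 0.0, 0.0, np.zeros(2), np.zeros(2), np.zeros(2),
                      table1)
        for j in J:
            assert np.allclose(j, 0.0)

    def test_chemotaxis_up_signal_gradient(self, table1):
        grad_c = np.array([1.0, 0.0])
        J_N, *_ = me.fluxes(1e4, 0.0, 1e-8, np.zeros(2), np.zeros(2),
                            grad_c, table1)
        assert J_N[0] > 0 and J_N[1] == 0.0

    def test_collagen_never_transported(self, table1):
        rng = np.random.default_rng(0)
        *_, J_rho = me.fluxes(1e4, 1e3, 1e-8, rng.normal(size=2),
                              rng.normal(size=2), rng.normal(size=2), table1)
        assert np.all(J_rho == 0.0)


class TestStress:
    def test_undeformed_stress_free(self, table1):
        s2, szz = me.cauchy_stress(np.zeros((2, 2)), 0.1, table1)
        assert np.allclose(s2, 0.0, atol=1e-14) and szz == pytest.approx(0.0)

    def test_moduli_values(self):
        # E=100, rho=0.1, nu=0.49 -> C1 = 10/5.96, D1 = 10/0.12
        p = par.DimensionalParameters(E=100.0, nu=0.49)
        rho = 0.1
        C1 = p.E * rho / (4 * (1 + p.nu))
        D1 = p.E * rho / (6 * (1 - 2 * p.nu))
        assert C1 == pytest.approx(1.6778523489932886)
        assert D1 == pytest.approx(83.33333333333333)

    def test_small_strain_matches_plane_strain_hooke(self, table1):
        """For ||grad u|| -> 0 the neo-Hookean law linearises to Hooke's
        law with Young's modulus E rho and Poisson ratio nu."""
        rho = 0.1
        eps_mag = 1e-6
        eps = eps_mag * np.array([[1.0, 0.3], [0.3, -0.5]])
        s2, szz = me.cauchy_stress(eps, rho, table1)   # grad u symmetric
        E_eff = table1.E * rho
        nu = table1.nu
        lam = E_eff * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E_eff / (2 * (1 + nu))
        hooke = lam * np.trace(eps) * np.eye(2) + 2 * mu * eps
        assert np.allclose(s2, hooke, rtol=1e-4,
                           atol=1e-4 * np.abs(hooke).max())
        assert szz == pytest.approx(lam * np.trace(eps), rel=1e-3)

    def test_frame_indifference(self, table1):
        """cauchy_stress(R . deformation) = R sigma R^T for rotations R."""
        rng = np.random.default_rng(3)
        F = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
        assert np.linalg.det(F) > 0
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        grad_u = np.eye(2) - np.linalg.inv(F)
        grad_u_rot = np.eye(2) - np.linalg.inv(R @ F)
        s, _ = me.cauchy_stress(grad_u, 0.1, table1)
        s_rot, _ = me.cauchy_stress(grad_u_rot, 0.1, table1)
        assert np.allclose(s_rot, R @ s @ R.T, atol=1e-10)

    def test_symmetry_and_positive_detB(self, table1):
        rng = np.random.default_rng(7)
        grad_u = 0.3 * rng.normal(size=(2, 2))
        B2, _ = me.left_cauchy_green(grad_u)
        assert np.linalg.det(B2) > 0
        s2, _ = me.cauchy_stress(grad_u, 0.2, table1)
        assert s2[0, 1] == pytest.approx(s2[1, 0], rel=1e-12)

    def test_singular_deformation_raises(self, table1):
        with pytest.raises(me.MechanicsFailure):
            me.cauchy_stress(np.eye(2), 0.1, table1)    # F^{-1} = 0


class TestBodyForce:
    def test_vanishes_without_myofibroblasts(self, table1):
        assert me.body_force_potential(0.0, 0.1, table1) == 0.0

    def test_maximal_at_saturation_constant(self, table1):
        rho0 = table1.R_rho_const      # 0.3
        h = 1e-6
        up = me.body_force_potential(1.0, rho0 + h, table1)
        dn = me.body_force_potential(1.0, rho0 - h, table1)
        assert (up - dn) / (2 * h) == pytest.approx(0.0, abs=1e-6)
        assert me.body_force_potential(1.0, rho0, table1) > \
            me.body_force_potential(1.0, 2 * rho0, table1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(M=st.floats(0, 1e6), rho=st.floats(0, 10))
    def test_nonnegative(self, M, rho):
        p = par.DimensionalParameters()
        assert me.body_force_potential(M, rho, p) >= 0.0
        assert me.mmp_level(M, 0.0, rho, p.a_c_III) >= 0.0


class TestRobinTraction:
    def test_examples(self):
        assert np.allclose(me.robin_traction(np.zeros(2), 0.1, [1, 0], 1e3),
                           0.0)
        t = me.robin_traction(np.array([0.01, 0.0]), 0.1, [1, 0], 1e3)
        assert np.allclose(t, [-1.0, 0.0])

    def test_linear_in_collagen(self):
        u = np.array([0.02, -0.01])
        t1 = me.robin_traction(u, 0.1, [0, 1], 1e3)
        t2 = me.robin_traction(u, 0.2, [0, 1], 1e3)
        assert np.allclose(t2, 2 * t1)
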
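"""Order-parameter dynamics, stationary states and bifurcation analysis."""

import numpy as np
import pytest
from scipy.linalg import expm

from doublering.model import CouplingParams, ExternalInputSeries
from doublering.meanfield import (
    AmplitudeInstabilityError,
    OrderParamState,
    _integrals,
    _rhs_array,
    bifurcation_curve,
    homogeneous_fixed_point,
    homogeneous_jacobian,
    homogeneous_stability,
    integrate_meanfield,
    numeric_jacobian,
    order_param_rhs,
    stationary_bump,
)

TWO_PI = 2 * np.pi


def brute_force_integrals(r0, rA, rB, psiA, psiB, u5, phi, cp, dens,
                          n_theta=200):
    """Independent 4-D Riemann-sum oracle for the population integrals."""
    th = TWO_PI * (np.arange(n_theta) + 0.5) / n_theta
    TA, TB = np.meshgrid(th, th, indexing="ij")
    rho = (1 + dens.chi * np.cos(TA - TB)) / n_theta**2
    C0, CA, CB, eA, eB = u5
    M0 = M0A = M0B = 0.0
    K_A = K_B = 0.0j
    for a, b in zip(dens.eta_A_grid, dens.eta_B_grid):
        I = (C0 + cp.j0 * r0 + CA * a + CB * b
             + cp.js_A * a * rA * np.cos(TA - psiA)
             + eA * a * np.cos(TA - phi)
             + cp.js_B * b * rB * np.cos(TB - psiB)
             + cp.j_a * b * rA * np.cos(TB - psiA)
             + eB * b * np.cos(TB - phi))
        F = np.clip(I, 0, None)
        M0 += dens.w_eta * np.sum(rho * F)
        M0A += dens.w_eta * a * np.sum(rho * F)
        M0B += dens.w_eta * b * np.sum(rho * F)
        K_A += dens.w_eta * a * np.sum(rho * F * np.exp(1j * TA))
        K_B += dens.w_eta * b * np.sum(rho * F * np.exp(1j * TB))
    return M0, K_A, K_B, M0A, M0B


class TestRhs:
    def test_zero_at_homogeneous_fixed_point(self, data_density,
                                             subcritical_couplings):
        cp = subcritical_couplings
        r0, _ = homogeneous_fixed_point(cp, 1.0, 0.5, 0.2, data_density)
        # auxiliary order parameters at the fixed point
        M0, _, _, M0A, M0B = _integrals(r0, 0, 0, 0, 0,
                                        (1.0, 0.5, 0.2, 0.0, 0.0), 0.0,
                                        cp, data_density)
        state = OrderParamState(r0, 0, 0, 0, 0, M0A, M0B)
        d = order_param_rhs(state, cp,
                            np.array([1.0, 0.5, 0.2, 0.0, 0.0]),
                            data_density)
        assert np.abs(d).max() < 1e-10

    def test_matches_brute_force_riemann_oracle(self, data_density):
        cp = CouplingParams(-0.5, 1.5, 3.0, 0.5)
        state = (1.2, 0.4, 0.6, 0.3, 1.1)
        u5 = np.array([0.5, 0.3, 0.2, 0.4, 0.1])
        got = _integrals(*state, u5, 0.7, cp, data_density)
        exp = brute_force_integrals(*state, u5, 0.7, cp, data_density)
        for g, e in zip(got, exp):
            assert abs(g - e) <= 1e-4 * max(abs(e), 1e-3)

    def test_linear_regime_matches_closed_form(self, data_density):
        # all inputs above threshold: the integrals reduce to the
        # moment-weighted linear system
        d = data_density
        cp = CouplingParams(0.3, 0.7, 1.1, 0.4)
        r0, rA, rB = 2.0, 0.1, 0.15
        u5 = np.array([1.5, 0.4, 0.3, 0.2, 0.1])
        got = _rhs_array(np.array([r0, rA, rB, 0.0, 0.0, 0.5, 0.6]),
                         cp, u5, 0.0, d, 0.025)
        zA = cp.js_A * rA + u5[3]
        zB = cp.js_B * rB + cp.j_a * rA + u5[4]
        M0 = u5[0] + cp.j0 * r0 + u5[1] * d.mean_eta_A \
            + u5[2] * d.mean_eta_B
        KA = d.F_AA * zA + d.F_AB * zB
        KB = d.F_BB * zB + d.F_AB * zA
        tau = 0.025
        assert abs(got[0] - (-r0 + M0) / tau) < 1e-8
        assert abs(got[1] - (-rA + KA) / tau) < 1e-8
        assert abs(got[2] - (-rB + KB) / tau) < 1e-8

    def test_phase_derivative_frozen_below_floor(self, data_density):
        state = OrderParamState(1.0, 0.0, 0.0, 1.0, 2.0, 0.3, 0.3)
        d = order_param_rhs(state, CouplingParams(0, 1, 1, 0),
                            np.array([1.0, 0, 0, 0.5, 0.5]), data_density)
        assert d[3] == 0.0 and d[4] == 0.0


class TestIntegration:
    def test_converges_to_homogeneous_fixed_point(self, data_density):
        cp = CouplingParams(0.5, 0.3, 0.4, 0.1)
        inp = ExternalInputSeries.constant(0.005, 240, C0=1.0, CA=1.0)
        traj = integrate_meanfield(OrderParamState(), cp, inp,
                                   data_density)
        r0_star, _ = homogeneous_fixed_point(cp, 1.0, 1.0, 0.0,
                                             data_density)
        assert abs(traj.r0[-1] - r0_star) / r0_star < 1e-6
        assert traj.r_A[-1] < 1e-6 and traj.r_B[-1] < 1e-6

    def test_step_halving_changes_little(self, data_density,
                                         subcritical_couplings):
        inp = ExternalInputSeries.constant(0.005, 60, C0=1.0, eps_A=0.5)
        t1 = integrate_meanfield(OrderParamState(), subcritical_couplings,
                                 inp, data_density, max_step=1e-3)
        t2 = integrate_meanfield(OrderParamState(), subcritical_couplings,
                                 inp, data_density, max_step=5e-4)
        rel = np.abs(t1.as_matrix() - t2.as_matrix()).max() \
            / max(t1.as_matrix().max(), 1e-12)
        assert rel < 1e-6

    def test_linear_regime_matches_matrix_exponential(self, data_density):
        # fully linear 5-dim system solved exactly via expm
        d = data_density
        cp = CouplingParams(0.2, 0.5, 0.8, 0.3)
        u5 = np.array([2.0, 0.5, 0.4, 0.3, 0.2])
        tau = 0.025
        mA, mB = d.mean_eta_A, d.mean_eta_B
        qA, qB = d.msq_eta_A, d.msq_eta_B
        cross = float(np.mean(d.eta_A_grid * d.eta_B_grid))
        FAA, FBB, FAB = d.F_AA, d.F_BB, d.F_AB
        A = np.array([
            [cp.j0 - 1, 0, 0, 0, 0],
            [0, cp.js_A * FAA + cp.j_a * FAB - 1, cp.js_B * FAB, 0, 0],
            [0, cp.js_A * FAB + cp.j_a * FBB, cp.js_B * FBB - 1, 0, 0],
            [cp.j0 * mA, 0, 0, -1, 0],
            [cp.j0 * mB, 0, 0, 0, -1],
        ]) / tau
        b = np.array([
            u5[0] + mA * u5[1] + mB * u5[2],
            FAA * u5[3] + FAB * u5[4],
            FAB * u5[3] + FBB * u5[4],
            mA * u5[0] + qA * u5[1] + cross * u5[2],
            mB * u5[0] + cross * u5[1] + qB * u5[2],
        ]) / tau
        x0 = np.array([1.0, 0.05, 0.08, 0.3, 0.35])
        T = 0.05
        x_star = -np.linalg.solve(A, b)
        x_exact = x_star + expm(A * T) @ (x0 - x_star)
        inp = ExternalInputSeries.constant(0.005, 10, *u5)
        traj = integrate_meanfield(
            OrderParamState(x0[0], x0[1], x0[2], 0, 0, x0[3], x0[4]),
            cp, inp, d)
        got = traj.as_matrix()[-1]
        assert np.abs(got - x_exact).max() < 1e-8

    def test_subcritical_bump_decays(self, data_density,
                                     subcritical_couplings):
        inp = ExternalInputSeries.constant(0.005, 300, C0=1.0)
        init = OrderParamState(1.0, 0.4, 0.4, 0.3, 0.3, 0.3, 0.3)
        traj = integrate_meanfield(init, subcritical_couplings, inp,
                                   data_density)
        assert traj.r_A[-1] < 1e-6 and traj.r_B[-1] < 1e-6


class TestHomogeneousState:
    def test_closed_form_examples(self, data_density):
        r0, _ = homogeneous_fixed_point(CouplingParams(), 1.0, 0.0, 0.0,
                                        data_density)
        assert np.isclose(r0, 1.0)
        r0, _ = homogeneous_fixed_point(CouplingParams(j0=0.5), 1.0, 0.0,
                                        0.0, data_density)
        assert np.isclose(r0, 2.0)

    def test_moment_weighted_input(self, data_density):
        cp = CouplingParams(j0=0.2)
        r0, prof = homogeneous_fixed_point(cp, 1.0, 1.0, 0.0,
                                           data_density)
        assert np.isclose(r0, (1.0 + data_density.mean_eta_A) / 0.8)
        # profile at eta=0: relu(C0 + j0 r0)
        assert np.isclose(prof(0.0, 0.0), 1.0 + 0.2 * r0)

    def test_amplitude_instability(self, data_density):
        with pytest.raises(AmplitudeInstabilityError):
            homogeneous_fixed_point(CouplingParams(j0=1.0), 1.0, 0, 0,
                                    data_density)


class TestStability:
    def test_uncoupled_network_is_stable(self, data_density):
        res = homogeneous_stability(CouplingParams(), data_density)
        assert res.stable

    def test_uniform_participation_critical_jsB_is_two(self,
                                                       uniform_density):
        below = homogeneous_stability(
            CouplingParams(0, 0, 2.0 - 1e-9, 0), uniform_density)
        above = homogeneous_stability(
            CouplingParams(0, 0, 2.0 + 1e-9, 0), uniform_density)
        assert below.stable and not above.stable

    def test_numeric_jacobian_agrees_with_closed_form(self, data_density):
        for cp in (CouplingParams(-0.5, 1.0, 3.0, 0.5),
                   CouplingParams(0.3, 4.0, 8.0, 1.0)):
            J_a = homogeneous_jacobian(cp, data_density)
            J_n = numeric_jacobian(cp, data_density)
            assert np.abs(J_a - J_n).max() < 1e-6

    def test_boundary_curve_monotone_for_data_density(self, data_density):
        jsA = np.linspace(0.0, 4.0, 6)
        curve = bifurcation_curve(0.0, data_density, jsA)
        crit = curve.js_B_critical
        assert np.all(np.isfinite(crit))
        assert np.all(np.diff(crit) < 0)


class TestBifurcationCurve:
    def test_uniform_eta_critical_value(self, uniform_density):
        curve = bifurcation_curve(0.0, uniform_density, [0.0])
        assert abs(curve.js_B_critical[0] - 2.0) < 1e-6

    def test_asymmetric_coupling_promotes_instability(self,
                                                      data_density):
        jsA = np.linspace(0.0, 2.0, 4)
        c0 = bifurcation_curve(0.0, data_density, jsA).js_B_critical
        c1 = bifurcation_curve(0.5, data_density, jsA).js_B_critical
        assert np.all(c1 < c0)

    def test_returned_points_sit_on_the_boundary(self, data_density):
        jsA = [0.5, 1.5]
        curve = bifurcation_curve(0.0, data_density, jsA, tol=1e-8)
        for a, b in zip(jsA, curve.js_B_critical):
            lo = homogeneous_stability(CouplingParams(0, a, b - 1e-6, 0),
                                       data_density)
            hi = homogeneous_stability(CouplingParams(0, a, b + 1e-6, 0),
                                       data_density)
            assert lo.stable and not hi.stable

    def test_phase_diagram_mask_matches_inequalities(self, data_density):
        jsA = np.linspace(0, 3, 4)
        jsB = np.linspace(0, 12, 5)
        pdg = bifurcation_curve(0.0, data_density, jsA, js_B_grid=jsB)
        for i, a in enumerate(jsA):
            for j, b in enumerate(jsB):
                assert pdg.stable_mask[i, j] == homogeneous_stability(
                    CouplingParams(0, a, b, 0), data_density).stable


class TestStationaryBump:
    def test_subcritical_collapses_to_homogeneous(self, data_density,
                                                  subcritical_couplings):
        st = stationary_bump(subcritical_couplings, (1.0, 0, 0),
                             data_density, psi_seed=0.7)
        r0_star, _ = homogeneous_fixed_point(subcritical_couplings, 1.0,
                                             0, 0, data_density)
        assert st.r_A < 1e-8 and st.r_B < 1e-8
        assert abs(st.r0 - r0_star) < 1e-8

    def test_supercritical_bump_is_seed_independent_up_to_rotation(
            self, uniform_density):
        cp = CouplingParams(-0.2, 0.0, 3.0, 0.0)
        s1 = stationary_bump(cp, (1.0, 0, 0), uniform_density,
                             psi_seed=0.5)
        s2 = stationary_bump(cp, (1.0, 0, 0), uniform_density,
                             psi_seed=2.0)
        assert s1.r_B > 0.1
        assert abs(s1.r_B - s2.r_B) < 1e-8
        assert abs(s1.r0 - s2.r0) < 1e-8
        assert np.isclose(s1.psi_B, 0.5) and np.isclose(s2.psi_B, 2.0)

    def test_bump_is_fixed_point_of_the_dynamics(self, uniform_density):
        cp = CouplingParams(-0.2, 0.0, 3.0, 0.0)
        st = stationary_bump(cp, (1.0, 0, 0), uniform_density,
                             psi_seed=0.0, tol=1e-13)
        d = order_param_rhs(st, cp, np.array([1.0, 0, 0, 0, 0]),
                            uniform_density)
        assert np.abs(d).max() < 1e-8


class TestRotationalEquivariance:
    def test_shifting_input_direction_shifts_phases_only(self,
                                                         data_density):
        cp = CouplingParams(-0.5, 1.0, 3.0, 0.3)
        delta = TWO_PI / 8  # grid-commensurate rotation
        out = []
        for phi in (0.0, delta):
            inp = ExternalInputSeries.constant(
                0.005, 80, C0=1.0, eps_A=0.8, eps_B=0.5, phi_ext=phi)
            init = OrderParamState(psi_A=phi, psi_B=phi)
            out.append(integrate_meanfield(init, cp, inp, data_density))
        t0, t1 = out
        np.testing.assert_allclose(t1.r_A, t0.r_A, atol=1e-8)
        np.testing.assert_allclose(t1.r_B, t0.r_B, atol=1e-8)
        np.testing.assert_allclose(t1.r0, t0.r0, atol=1e-8)
        sel = t0.r_A > 1e-3
        dpsi = np.angle(np.exp(1j * (t1.psi_A[sel] - t0.psi_A[sel])))
        np.testing.assert_allclose(dpsi, delta, atol=1e-8)
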
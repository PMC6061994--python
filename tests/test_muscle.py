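"""Hill-type muscle: curves, equilibrium, geometry, and energetics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from muskel import muscle as mu
from muskel.components import ModelError
from muskel.synthetic import make_pendulum, make_planar_arm
from muskel.system import State, build_system, default_state

P = mu.MusculotendonParams()


class TestCharacteristicCurves:
    def test_anchor_values_exact(self):
        assert mu.active_force_length(1.0, P.gamma) == 1.0
        assert abs(mu.passive_force_length(1.0 + P.e_0, P.k_p, P.e_0) - 1.0) < 1e-12
        assert mu.force_velocity(0.0, P.a_f, P.f_ecc) == 1.0
        assert mu.force_velocity(-1.0, P.a_f, P.f_ecc) == 0.0
        assert abs(mu.tendon_force_strain(P.e_T0, P.e_T0) - 1.0) < 1e-12

    def test_active_curve_formula_value(self):
        # exp(-0.09 / 0.45)
        assert abs(mu.active_force_length(1.3, 0.45) - 0.818730753077982) < 1e-12

    def test_passive_curve_formula_value(self):
        # (e^2 - 1) / (e^4 - 1)
        expected = (math.e**2 - 1.0) / (math.e**4 - 1.0)
        assert abs(mu.passive_force_length(1.35, 4.0, 0.7) - expected) < 1e-12
        assert mu.passive_force_length(0.9, 4.0, 0.7) == 0.0

    @given(d=st.floats(0.0, 0.9))
    def test_active_curve_symmetric_about_optimum(self, d):
        assert mu.active_force_length(1.0 - d) == pytest.approx(
            mu.active_force_length(1.0 + d), abs=1e-15)

    def test_eccentric_plateau_approached(self):
        f10 = mu.force_velocity(10.0, P.a_f, P.f_ecc)
        assert abs(f10 - P.f_ecc) / P.f_ecc < 0.02

    def test_force_velocity_c1_continuous_at_zero(self):
        h = 1e-7
        slope_minus = (mu.force_velocity(0.0) - mu.force_velocity(-h)) / h
        slope_plus = (mu.force_velocity(h) - mu.force_velocity(0.0)) / h
        assert abs(slope_plus - slope_minus) < 1e-5

    def test_tendon_mid_toe_matches_documented_form(self):
        # independent evaluation of the exponential-toe expression
        e, k_toe = P.e_T0 / 2.0, 3.0
        expected = (math.exp(k_toe * e / P.e_T0) - 1.0) / (math.exp(k_toe) - 1.0)
        assert abs(mu.tendon_force_strain(e, P.e_T0) - expected) < 1e-15
        assert mu.tendon_force_strain(-0.01, P.e_T0) == 0.0

    def test_curve_ranges_over_random_inputs(self, rng):
        lm = rng.uniform(0.3, 2.0, size=10_000)
        vm = rng.uniform(-3.0, 3.0, size=10_000)
        eps = rng.uniform(-0.1, 0.3, size=10_000)
        for x in lm:
            assert 0.0 < mu.active_force_length(x) <= 1.0
            assert mu.passive_force_length(x) >= 0.0
        for v in vm:
            f = mu.force_velocity(v)
            assert 0.0 <= f < P.f_ecc + 1e-12
        for e in eps:
            assert mu.tendon_force_strain(e) >= 0.0

    def test_force_velocity_inverse_round_trip(self, rng):
        for f in rng.uniform(0.01, P.f_ecc - 0.01, size=200):
            v, clamped = mu.force_velocity_inverse(f)
            assert not clamped
            assert abs(mu.force_velocity(v) - f) < 1e-12


class TestActivationDynamics:
    def test_fixed_point(self):
        assert mu.activation_derivative(0.42, 0.42, 0.01, 0.04) == 0.0

    def test_formula_value(self):
        assert mu.activation_derivative(1.0, 0.5, 0.01, 0.04) == pytest.approx(50.0)

    @pytest.mark.parametrize("u,a0", [(0.9, 0.1), (0.05, 0.8)])
    def test_matches_closed_form_exponential(self, u, a0):
        tau = P.tau_act if u > a0 else P.tau_deact
        sol = solve_ivp(lambda t, a: mu.activation_derivative(u, a[0], P.tau_act, P.tau_deact),
                        (0.0, 1.0), [a0], t_eval=np.linspace(0, 1, 101),
                        rtol=1e-10, atol=1e-12)
        exact = u + (a0 - u) * np.exp(-sol.t / tau)
        assert np.max(np.abs(sol.y[0] - exact)) < 1e-6


class TestPathGeometry:
    def test_fixed_ground_segment(self):
        system = build_system(make_pendulum(1))
        st = default_state(system)
        path = [("ground", np.array([0.0, 0.0, 0.0])), ("ground", np.array([0.3, 0.0, 0.0]))]
        l, v = mu.path_length_and_speed(path, system, st)
        assert l == pytest.approx(0.3)
        assert v == 0.0

    def test_three_point_additivity(self):
        system = build_system(make_pendulum(1))
        st = default_state(system)
        pts = [np.zeros(3), np.array([0.1, 0.2, 0.0]), np.array([0.4, -0.1, 0.2])]
        path3 = [("ground", p) for p in pts]
        l3, _ = mu.path_length_and_speed(path3, system, st)
        l12, _ = mu.path_length_and_speed(path3[:2], system, st)
        l23, _ = mu.path_length_and_speed(path3[1:], system, st)
        assert l3 == pytest.approx(l12 + l23, abs=1e-15)

    def test_zero_length_segment_rejected(self):
        system = build_system(make_pendulum(1))
        st = default_state(system)
        path = [("ground", np.zeros(3)), ("ground", np.zeros(3))]
        with pytest.raises(ModelError, match="zero-length"):
            mu.path_length_and_speed(path, system, st)

    def test_speed_matches_finite_difference(self, arm_system, rng):
        m = arm_system.muscles[0]
        q = rng.normal(size=2) * 0.5
        u = rng.normal(size=2)
        h = 1e-6
        st = State(0.0, q, u, np.zeros(arm_system.nz))
        _, v = mu.path_length_and_speed(m.path, arm_system, st)
        lp, _ = mu.path_length_and_speed(
            m.path, arm_system, State(0.0, q + h * u, u, np.zeros(arm_system.nz)))
        lm, _ = mu.path_length_and_speed(
            m.path, arm_system, State(0.0, q - h * u, u, np.zeros(arm_system.nz)))
        assert v == pytest.approx((lp - lm) / (2 * h), rel=1e-6, abs=1e-9)


class TestMomentArm:
    def test_path_not_crossing_joint_is_zero(self, arm_system):
        st = default_state(arm_system)
        path = [("ground", np.array([0.5, 0.0, 0.0])), ("ground", np.array([0.5, -0.3, 0.0]))]
        assert abs(mu.moment_arm(path, arm_system, st, "elbow")) < 1e-12

    def test_geometric_lever_arm_perpendicular_configuration(self):
        """Origin at perpendicular distance d from a pin axis, insertion along
        the second link: |r| approaches d when the path runs perpendicular."""
        system = build_system(make_pendulum(1, lengths=[1.0]))
        st = default_state(system)
        d = 0.07
        # path from a ground point level with the pin, offset d along -y,
        # to a point far down the link: nearly perpendicular lever
        path = [("ground", np.array([0.0, -d, 0.0])), ("link1", np.array([0.0, -0.9, 0.0]))]
        st.q[:] = np.pi / 2  # link horizontal: path exactly perpendicular to link
        r = mu.moment_arm(path, system, st, 0)
        assert abs(abs(r) - d) < 1e-3

    def test_virtual_work_consistency(self, arm_system, rng):
        st = State(0.0, np.array([0.3, 0.7]), np.zeros(2), np.zeros(arm_system.nz))
        for m in arm_system.muscles:
            tau = mu.path_generalized_force(m.path, arm_system, st, 1.0)
            for j in range(arm_system.nq):
                r = mu.moment_arm(m.path, arm_system, st, j)
                if abs(r) > 1e-6:
                    assert abs(r - tau[j]) / abs(r) < 1e-6
                else:
                    assert abs(r - tau[j]) < 1e-8


class TestRigidTendon:
    def test_maximal_isometric_conditions(self):
        p = replace(P, alpha_opt=0.0)
        out = p and mu.rigid_tendon_force(p, 1.0, p.l_Ts + p.l_opt, 0.0)
        assert out.force == pytest.approx(p.F_max)

    def test_pennation_scales_force_by_cosine(self):
        p = replace(P, alpha_opt=0.3)
        h = p.width
        l_MT = p.l_Ts + math.sqrt(p.l_opt**2 - h**2)  # fiber exactly at l_opt
        out = mu.rigid_tendon_force(p, 1.0, l_MT, 0.0)
        assert out.norm_fiber_length == pytest.approx(1.0)
        assert out.force == pytest.approx(p.F_max * math.cos(0.3), rel=1e-12)

    def test_low_activation_short_fiber(self):
        p = replace(P, alpha_opt=0.0)
        l_MT = p.l_Ts + 0.9 * p.l_opt
        out = mu.rigid_tendon_force(p, p.a_min, l_MT, 0.0)
        expected = p.F_max * p.a_min * mu.active_force_length(0.9, p.gamma)
        assert out.f_PE == 0.0
        assert out.force == pytest.approx(expected, rel=1e-12)

    def test_impossible_pennation_rejected(self):
        p = replace(P, alpha_opt=0.5)
        with pytest.raises(ModelError, match="pennation"):
            mu.rigid_tendon_force(p, 1.0, p.l_Ts, 0.0)


class TestCompliantEquilibrium:
    def test_solver_matches_bisection_oracle(self):
        for a in (0.2, 0.6, 1.0):
            l_MT = P.l_Ts * 1.02 + P.l_opt
            l_M = mu.init_fiber_length(P, a, l_MT)
            res, _, _ = mu.fiber_equilibrium_and_derivative(P, a, l_M, l_MT)
            assert abs(res) < 1e-9

            def g(lm):
                r, _, _ = mu.fiber_equilibrium_and_derivative(P, a, lm, l_MT)
                # isometric residual: tendon vs active+passive at v = 0
                cos_a = math.cos(mu._pennation(P, lm)[1])
                return (mu.tendon_force_strain((l_MT - lm * cos_a) / P.l_Ts - 1.0, P.e_T0)
                        - (a * mu.active_force_length(lm / P.l_opt, P.gamma)
                           + mu.passive_force_length(lm / P.l_opt, P.k_p, P.e_0)) * cos_a)

            l_M_bisect = bisect(g, 0.05 * P.l_opt, 2.2 * P.l_opt, xtol=1e-14)
            assert abs(l_M - l_M_bisect) < 1e-8

    def test_residual_below_tolerance_across_states(self, rng):
        for _ in range(200):
            a = rng.uniform(P.a_min, 1.0)
            l_M = rng.uniform(0.6, 1.6) * P.l_opt
            l_MT = rng.uniform(1.0, 1.1) * P.l_Ts + l_M
            res, _, out = mu.fiber_equilibrium_and_derivative(P, a, l_M, l_MT)
            if not out.clamped:
                assert abs(res) < 1e-9

    def test_slack_tendon_max_shortening(self):
        # tendon slack and no passive force: force-velocity target 0 -> v = -1
        l_M = 0.95 * P.l_opt
        l_MT = 0.5 * P.l_Ts + l_M  # tendon far below slack length
        _, l_M_dot, out = mu.fiber_equilibrium_and_derivative(P, 1.0, l_M, l_MT)
        assert out.f_T == 0.0
        assert out.norm_fiber_velocity == pytest.approx(-1.0)
        assert l_M_dot == pytest.approx(-P.l_opt * P.v_max)

    def test_no_bracket_raises(self):
        with pytest.raises(ModelError, match="bracket"):
            mu.init_fiber_length(P, 1.0, 10.0 * (P.l_Ts + P.l_opt))

    def test_stiff_tendon_limit_matches_rigid_on_ramp(self):
        """Compliant force approaches the rigid-tendon force as tendon strain
        capacity shrinks (ramp stretch, transients after the velocity steps
        excluded)."""
        p_rigid = mu.MusculotendonParams(F_max=100.0, l_opt=0.05, l_Ts=0.1, v_max=10.0)
        p_stiff = replace(p_rigid, e_T0=1e-4)
        l0 = p_stiff.l_Ts + 0.95 * p_stiff.l_opt
        A, T_ramp = 0.01, 0.5

        def lmt(t):
            return l0 + A * min(t / T_ramp, 1.0)

        lm0 = mu.init_fiber_length(p_stiff, 1.0, l0)
        sol = solve_ivp(
            lambda t, y: [mu.fiber_equilibrium_and_derivative(p_stiff, 1.0, y[0], lmt(t))[1]],
            (0.0, 0.8), [lm0], t_eval=np.linspace(0, 0.8, 81), rtol=1e-8, atol=1e-12,
            method="LSODA", max_step=5e-3)
        f_compliant = np.array([
            mu.fiber_equilibrium_and_derivative(p_stiff, 1.0, lm, lmt(t))[2].force
            for t, lm in zip(sol.t, sol.y[0])])
        f_rigid = np.array([
            mu.rigid_tendon_force(p_rigid, 1.0, lmt(t), A / T_ramp if t < T_ramp else 0.0).force
            for t in sol.t])
        mask = ((sol.t > 0.02) & (sol.t < T_ramp - 0.01)) | (sol.t > T_ramp + 0.02)
        dev = np.abs(f_compliant - f_rigid)[mask] / f_rigid[mask]
        assert np.max(dev) < 0.01


class TestMetabolicRate:
    ISO = mu.MuscleOutputs(l_MT=0.3, v_MT=0.0, l_T=0.2, norm_fiber_length=1.0,
                           norm_fiber_velocity=0.0, pennation=0.0, f_L=1.0, f_V=1.0,
                           f_PE=0.0, f_T=1.0, force=1000.0, fiber_length=0.1,
                           fiber_velocity=0.0)

    def test_inactive_isometric_is_basal_only(self):
        rate = mu.metabolic_rate(P, self.ISO, a=0.0, muscle_mass=0.5, body_mass=70.0)
        assert rate == pytest.approx(1.2 * 70.0)

    def test_isometric_maximal_formula(self):
        rate = mu.metabolic_rate(P, self.ISO, a=1.0, muscle_mass=0.5, body_mass=70.0)
        assert rate == pytest.approx(0.5 * (40.0 + 74.0) + 1.2 * 70.0)

    def test_lengthening_has_no_shortening_heat(self):
        out = replace(self.ISO, norm_fiber_velocity=0.5, fiber_velocity=0.05, f_V=1.3)
        rate = mu.metabolic_rate(P, out, a=1.0, muscle_mass=0.5)
        # only activation + maintenance heat (work term negative, clamped)
        assert rate == pytest.approx(0.5 * (40.0 + 74.0))

    def test_negative_mass_rejected(self):
        with pytest.raises(ModelError):
            mu.metabolic_rate(P, self.ISO, a=0.5, muscle_mass=-1.0)

    def test_never_below_basal(self, rng):
        for _ in range(100):
            out = replace(self.ISO, norm_fiber_velocity=rng.normal(),
                          fiber_velocity=rng.normal() * 0.1,
                          f_L=rng.uniform(0, 1), f_V=rng.uniform(0, 1.4))
            rate = mu.metabolic_rate(P, out, a=rng.uniform(0, 1), muscle_mass=0.5,
                                     body_mass=70.0)
            assert rate >= 1.2 * 70.0 - 1e-12
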
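"""Forward integration, IK, ID, static optimization, and CMC-lite."""

import numpy as np
import pytest

from muskel import muscle as mu
from muskel.components import (
    ModelError,
    ModelSpec,
    make_body,
    make_ground,
    make_joint,
    make_muscle,
)
from muskel.dataio import DataTable
from muskel.multibody import AppliedForces
from muskel.solvers import (
    CMCSettings,
    IKSettings,
    IntegratorSettings,
    SOSettings,
    StatesTrajectory,
    cmc_step,
    integrate_forward,
    make_reference,
    solve_id_trajectory,
    solve_ik_trajectory,
    static_optimization_frame,
)
from muskel.synthetic import make_pendulum, make_planar_arm, synth_markers
from muskel.system import State, build_system, default_state

from .oracles import GRAVITY


class TestIntegrateForward:
    def test_rest_at_equilibrium_stays(self):
        system = build_system(make_pendulum(1))
        traj = integrate_forward(system, default_state(system), 1.0,
                                 t_eval=np.linspace(0, 1, 11))
        assert np.max(np.abs(traj.q)) < 1e-12
        assert np.max(np.abs(traj.u)) < 1e-12

    def test_tolerance_tightening_convergence(self):
        system = build_system(make_pendulum(2))
        st = default_state(system)
        st.q[:] = [1.0, 0.5]
        finals = []
        for rtol in (1e-8, 1e-9):
            traj = integrate_forward(system, st, 2.0,
                                     settings=IntegratorSettings(rtol=rtol, atol=rtol * 1e-2),
                                     t_eval=[2.0])
            finals.append(np.concatenate([traj.q[-1], traj.u[-1]]))
        rel = np.linalg.norm(finals[0] - finals[1]) / np.linalg.norm(finals[1])
        assert rel < 1e-4

    def test_trajectory_times_strictly_increasing(self):
        system = build_system(make_pendulum(1))
        st = default_state(system)
        st.q[:] = 0.5
        traj = integrate_forward(system, st, 0.5)
        assert np.all(np.diff(traj.times) > 0)
        with pytest.raises(ModelError):
            StatesTrajectory(times=np.array([0.0, 0.0, 0.1]),
                             q=np.zeros((3, 1)), u=np.zeros((3, 1)), z=np.zeros((3, 0)))


@pytest.fixture(scope="module")
def arm_and_coords():
    model = make_planar_arm(2)
    system = build_system(model)
    t = np.linspace(0, 1, 60)
    coords = DataTable(
        time=t,
        columns={"shoulder": 0.4 * np.sin(4 * t), "elbow": 0.7 + 0.4 * np.cos(3 * t)},
        units={"shoulder": "rad", "elbow": "rad"}, meta={"inDegrees": False})
    return model, system, coords


class TestInverseKinematics:

    def test_noise_free_recovery(self, arm_and_coords):
        model, system, coords = arm_and_coords
        markers = synth_markers(model, coords, noise_sd=0.0, seed=0)
        res = solve_ik_trajectory(system, markers)
        for name in ("shoulder", "elbow"):
            err = res.table.columns[name] - coords.columns[name]
            assert np.sqrt(np.mean(err**2)) < 1e-6
        assert np.nanmax(res.rms) < 1e-8

    def test_weight_scaling_invariance(self, arm_and_coords):
        model, system, coords = arm_and_coords
        markers = synth_markers(model, coords, noise_sd=0.001, seed=5)
        res1 = solve_ik_trajectory(system, markers)
        doubled = {m.name: 2.0 * m.weight for m in system.mb.markers}
        res2 = solve_ik_trajectory(system, markers, IKSettings(weights=doubled))
        for name in ("shoulder", "elbow"):
            assert np.allclose(res1.table.columns[name], res2.table.columns[name],
                               atol=1e-8)

    def test_single_marker_pendulum_quarter_turn(self):
        model = make_pendulum(1, lengths=[1.0])
        system = build_system(model)
        markers = DataTable(time=[0.0], columns={"tip1": np.array([[1.0, 0.0, 0.0]])},
                            units={"tip1": "m"}, meta={"Units": "m"})
        res = solve_ik_trajectory(system, markers)
        assert res.table.columns["j1"][0] == pytest.approx(np.pi / 2, abs=1e-8)

    def test_unmatched_marker_dropped_with_warning(self, arm_and_coords):
        model, system, coords = arm_and_coords
        markers = synth_markers(model, coords, noise_sd=0.0, seed=0)
        markers.columns["ghost"] = np.zeros((markers.nrows, 3))
        markers.units["ghost"] = "m"
        with pytest.warns(UserWarning, match="ghost"):
            res = solve_ik_trajectory(system, markers)
        assert np.nanmax(res.rms) < 1e-8

    def test_mm_table_rejected_until_converted(self, arm_and_coords):
        model, system, coords = arm_and_coords
        markers = synth_markers(model, coords, noise_sd=0.0, seed=0)
        markers.meta["Units"] = "mm"
        with pytest.raises(ModelError, match="mm"):
            solve_ik_trajectory(system, markers)


class TestInverseDynamicsTrajectory:
    def test_static_pose_gives_gravity_compensation(self):
        m_kg, d = 1.5, 0.8
        system = build_system(make_pendulum(1, masses=[m_kg], lengths=[d], point_mass=True))
        t = np.linspace(0, 1, 21)
        theta = 0.6
        table = DataTable(time=t, columns={"j1": np.full_like(t, theta)},
                          units={"j1": "rad"}, meta={"inDegrees": False})
        tau = solve_id_trajectory(system, table)
        assert np.allclose(tau.columns["j1"], m_kg * GRAVITY * d * np.sin(theta), atol=1e-9)

    def test_zero_gravity_constant_velocity_slider(self):
        model = ModelSpec(name="slider")
        model.gravity = np.zeros(3)
        model.add(make_ground())
        model.add(make_body("cart", 2.0))
        model.add(make_joint("s", "slider", "/ground", "/cart", axis=(1, 0, 0)))
        system = build_system(model)
        t = np.linspace(0, 1, 21)
        table = DataTable(time=t, columns={"s": 0.3 * t}, units={"s": "m"},
                          meta={"inDegrees": False})
        tau = solve_id_trajectory(system, table)
        assert np.allclose(tau.columns["s"], 0.0, atol=1e-10)

    def test_forward_then_inverse_recovers_applied_torques(self):
        system = build_system(make_pendulum(2))
        st = default_state(system)
        st.q[:] = [0.3, -0.2]

        def tau_fn(t):
            return np.array([0.8 * np.sin(2 * np.pi * t), 0.4 * np.cos(2.6 * np.pi * t)])

        traj = integrate_forward(system, st, 2.0,
                                 settings=IntegratorSettings(rtol=1e-10, atol=1e-12),
                                 t_eval=np.linspace(0, 2, 401),
                                 applied=lambda t, _s: AppliedForces(generalized=tau_fn(t)))
        table = DataTable(time=traj.times,
                          columns={"j1": traj.q[:, 0], "j2": traj.q[:, 1]},
                          units={"j1": "rad", "j2": "rad"}, meta={"inDegrees": False})
        tau = solve_id_trajectory(system, table)
        applied = np.array([tau_fn(t) for t in traj.times])
        recovered = np.stack([tau.columns["j1"], tau.columns["j2"]], axis=1)
        rel_rms = (np.sqrt(np.mean((recovered - applied) ** 2))
                   / np.sqrt(np.mean(applied**2)))
        assert rel_rms < 0.01

    def test_missing_column_and_nonuniform_times_rejected(self):
        system = build_system(make_pendulum(2))
        t = np.linspace(0, 1, 11)
        table = DataTable(time=t, columns={"j1": np.zeros_like(t)}, units={"j1": "rad"},
                          meta={"inDegrees": False})
        with pytest.raises(ModelError, match="missing columns.*j2"):
            solve_id_trajectory(system, table)
        t2 = np.concatenate([t[:5], t[5:] + 0.05])
        table2 = DataTable(time=t2, columns={"j1": np.zeros_like(t2), "j2": np.zeros_like(t2)},
                           units={"j1": "rad", "j2": "rad"}, meta={"inDegrees": False})
        with pytest.raises(ModelError, match="non-uniform"):
            solve_id_trajectory(system, table2)


def single_muscle_pendulum():
    model = ModelSpec(name="one_muscle")
    model.add(make_ground())
    model.add(make_body("link1", 2.0, com=(0, -0.4, 0), inertia=np.diag([0.1, 0.0, 0.1])))
    model.add(make_joint("j1", "pin", "/ground", "/link1"))
    path = [("/ground", (0.08, 0.0, 0)), ("/link1", (0.06, -0.35, 0))]
    model.add(make_muscle("mus", path, rigid_tendon=True,
                          params=dict(F_max=800.0, l_opt=0.15, l_Ts=0.22, v_max=10.0)))
    return model


class TestStaticOptimization:
    def test_single_muscle_matches_analytic_kkt(self):
        system = build_system(single_muscle_pendulum())
        st = default_state(system)
        st.q[:] = 0.4
        m = system.muscles[0]
        # independent affine coefficients from the curve formulas
        l_MT, v_MT = mu.path_length_and_speed(m.path, system, st)
        lm = (l_MT - m.params.l_Ts) / m.params.l_opt
        c = m.params.F_max * mu.active_force_length(lm, m.params.gamma)
        d = m.params.F_max * mu.passive_force_length(lm, m.params.k_p, m.params.e_0)
        r = mu.path_generalized_force(m.path, system, st, 1.0)[0]  # virtual-work route
        W = 1e3
        for target in (2.0, -1.0, 8.0):
            res = static_optimization_frame(system, st, np.array([target]),
                                            SOSettings(reserve_penalty=W))
            a_star = W * r * c * (target - r * d) / (1.0 + W * r**2 * c**2)
            a_star = min(max(a_star, m.params.a_min), 1.0)
            assert abs(res.activations[0] - a_star) < 1e-6

    def test_identical_redundant_muscles_share_load_equally(self):
        model = single_muscle_pendulum()
        comp = model.find("/mus")
        path = [(bp, loc.copy()) for bp, loc in comp.get("path")]
        model.add(make_muscle("mus_twin", path, rigid_tendon=True,
                              params=dict(F_max=800.0, l_opt=0.15, l_Ts=0.22, v_max=10.0)))
        system = build_system(model)
        st = default_state(system)
        st.q[:] = 0.4
        res = static_optimization_frame(system, st, np.array([3.0]))
        assert abs(res.activations[0] - res.activations[1]) < 1e-8

    def test_target_beyond_capacity_saturates_and_reserves_absorb(self):
        system = build_system(single_muscle_pendulum())
        st = default_state(system)
        st.q[:] = 0.4
        res = static_optimization_frame(system, st, np.array([500.0]))
        assert res.activations[0] == pytest.approx(1.0, abs=1e-9)
        # reserve carries the remainder of the torque balance
        torque_from_muscle = res.moment_arms[0, 0] * res.muscle_forces[0]
        assert res.reserves[0] == pytest.approx(500.0 - torque_from_muscle)

    def test_matches_brute_force_grid_two_muscles(self, arm_system):
        from muskel.solvers import _muscle_affine_coeffs

        st = State(0.0, np.array([0.2, 0.9]), np.zeros(2), np.zeros(arm_system.nz))
        target = np.array([0.0, 2.0])
        res = static_optimization_frame(arm_system, st, target)
        c, d, R = _muscle_affine_coeffs(arm_system, st)
        grid = np.arange(0.01, 1.0 + 1e-12, 1e-3)
        A1, A2 = np.meshgrid(grid, grid, indexing="ij")
        cost = A1**2 + A2**2
        F1, F2 = c[0] * A1 + d[0], c[1] * A2 + d[1]
        for j in range(2):
            rho = target[j] - (R[0, j] * F1 + R[1, j] * F2)
            cost += 1e3 * rho**2
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        assert abs(grid[i] - res.activations[0]) < 2e-3
        assert abs(grid[j] - res.activations[1]) < 2e-3

    def test_nonquadratic_exponent_close_to_qp_at_p2(self, arm_system):
        st = State(0.0, np.array([0.1, 0.8]), np.zeros(2), np.zeros(arm_system.nz))
        target = np.array([0.5, 1.0])
        qp = static_optimization_frame(arm_system, st, target, SOSettings(p=2.0))
        pg = static_optimization_frame(arm_system, st, target, SOSettings(p=2.000001))
        assert np.allclose(qp.activations, pg.activations, atol=1e-4)


class TestCMC:
    def test_on_constant_reference_desired_acceleration_is_zero(self, arm_system):
        st = default_state(arm_system)
        st.q[:] = [0.1, 0.4]
        q0 = st.q.copy()
        ref = lambda t: (q0, np.zeros(2), np.zeros(2))
        _, so = cmc_step(arm_system, st, ref, 0.0, CMCSettings())
        # target torque equals pure gravity compensation: reserves + muscles
        # reproduce inverse dynamics at zero desired acceleration
        from muskel.multibody import inverse_dynamics

        tau_g = inverse_dynamics(arm_system, st, np.zeros(2))
        torque = so.moment_arms.T @ so.muscle_forces + so.reserves
        assert np.allclose(torque, tau_g, atol=1e-8)

    def test_zero_gains_pure_feedforward(self, arm_system):
        st = default_state(arm_system)
        st.q[:] = [0.3, 0.3]
        st.u[:] = [5.0, -5.0]  # far from the reference: must not matter
        settings = CMCSettings(kp=0.0, kv=0.0, lookahead=0.01)
        qdd = np.array([1.7, -0.4])
        ref = lambda t: (np.zeros(2), np.zeros(2), qdd)
        from muskel.multibody import forward_dynamics, inverse_dynamics

        _, so = cmc_step(arm_system, st, ref, 0.0, settings)
        torque = so.moment_arms.T @ so.muscle_forces + so.reserves
        assert np.allclose(torque, inverse_dynamics(arm_system, st, qdd), atol=1e-8)

    def test_excitation_inversion_reaches_desired_activation(self):
        p = mu.MusculotendonParams()
        from muskel.solvers import _invert_activation
        from scipy.integrate import solve_ivp

        for a0, a_des in ((0.1, 0.8), (0.9, 0.3), (0.5, 0.5)):
            T = 0.01
            u = _invert_activation(p, a0, a_des, T)
            sol = solve_ivp(lambda t, a: mu.activation_derivative(u, a[0], p.tau_act, p.tau_deact),
                            (0, T), [a0], rtol=1e-10, atol=1e-12)
            reached = sol.y[0, -1]
            if 0.0 < u < 1.0:  # not saturated: must land on the target
                assert reached == pytest.approx(a_des, abs=1e-6)
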
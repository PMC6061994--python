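"""Forward and inverse solvers operating on compiled systems.

* :func:`integrate_forward` — adaptive Runge-Kutta integration of the full
  state derivative (coordinates, speeds, muscle activations and compliant
  fiber lengths), with prescribed and reflex controllers;
* :func:`solve_ik_trajectory` — frame-by-frame weighted least-squares
  inverse kinematics on marker trajectories (damped Gauss-Newton, warm
  started in time order);
* :func:`solve_id_trajectory` — inverse dynamics over a coordinate
  trajectory with smoothed finite differencing;
* :func:`static_optimization_frame` — per-instant distribution of required
  joint torques among redundant rigid-tendon muscles (convex QP for the
  default squared-activation cost) with penalized reserve actuators;
* :func:`cmc_step` / :func:`track_cmc` — a simplified computed-muscle-control
  tracking loop ("CMC-lite"): PD feedback on the reference trajectory,
  inverse dynamics for the target torques, static optimization for the
  activations, and inversion of the activation dynamics for excitations
  over a short lookahead window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import lsq_linear

from . import muscle as _mu
from .components import ModelError
from .controllers import DelayBuffer, ExcitationSignal, ReflexParams, stretch_reflex_excitation
from .dataio import DataTable
from .multibody import (
    AppliedForces,
    contact_force,
    coordinate_limit_force,
    forward_dynamics,
    inverse_dynamics,
)
from .system import State, SystemSpec

__all__ = [
    "SolverError",
    "IntegratorSettings",
    "IKSettings",
    "SOSettings",
    "CMCSettings",
    "StatesTrajectory",
    "build_controllers",
    "equilibrate_muscles",
    "integrate_forward",
    "solve_ik_trajectory",
    "solve_id_trajectory",
    "static_optimization_frame",
    "cmc_step",
    "make_reference",
    "track_cmc",
]


class SolverError(RuntimeError):
    pass


@dataclass
class IntegratorSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    method: str = "RK45"

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ModelError("integrator tolerances must be > 0")


@dataclass
class IKSettings:
    weights: Optional[dict] = None  # per-marker overrides
    grad_tol: float = 1e-10
    max_iter: int = 100
    warm_start: bool = True


@dataclass
class SOSettings:
    p: float = 2.0
    reserve_penalty: float = 1e3
    tol: float = 1e-10


@dataclass
class CMCSettings:
    kp: float = 100.0  # [1/s^2]
    kv: float = 20.0  # [1/s]
    lookahead: float = 0.01  # [s]
    apply_reserves: bool = True
    so: SOSettings = field(default_factory=SOSettings)


@dataclass
class StatesTrajectory:
    """Time-ordered sequence of states with a uniform layout."""

    times: np.ndarray
    q: np.ndarray  # (n, nq)
    u: np.ndarray  # (n, nu)
    z: np.ndarray  # (n, nz)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ModelError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def state(self, i: int) -> State:
        return State(float(self.times[i]), self.q[i].copy(), self.u[i].copy(), self.z[i].copy())

    def final_state(self) -> State:
        return self.state(len(self) - 1)


# ---------------------------------------------------------------------------
# runtime controllers


class PrescribedRuntime:
    def __init__(self, muscle_name: str, signal: ExcitationSignal):
        self.muscle = muscle_name
        self.signal = signal
        self.delay = None

    def excitation(self, t: float) -> float:
        return self.signal(t)

    def commit(self, t, system, state):
        pass


class ReflexRuntime:
    """Delayed stretch reflex bound to one muscle.

    Senses the muscle's normalized fiber lengthening velocity; the sensed
    history is committed to the delay buffer only at accepted integrator
    chunk boundaries, so excitation at time t depends exclusively on states
    at times <= t - delay.
    """

    def __init__(self, muscle_name: str, params: ReflexParams):
        self.muscle = muscle_name
        self.params = params
        self.buffer = DelayBuffer()
        self.delay = params.delay

    def excitation(self, t: float) -> float:
        return stretch_reflex_excitation(self.params, self.buffer, t)

    def commit(self, t, system, state):
        m = system.muscles[system.muscle_index(self.muscle)]
        l_MT, v_MT = _mu.path_length_and_speed(m.path, system, state)
        a = float(np.clip(state.z[m.a_slot], m.params.a_min, 1.0))
        if m.rigid_tendon:
            out = _mu.rigid_tendon_force(m.params, a, l_MT, v_MT)
        else:
            _, _, out = _mu.fiber_equilibrium_and_derivative(m.params, a, state.z[m.lm_slot], l_MT, v_MT)
        self.buffer.append(t, out.norm_fiber_velocity)


def build_controllers(model, system: SystemSpec) -> list:
    """Instantiate runtime controllers from the model's controller components."""
    paths = dict(model.walk())
    out = []
    for p, comp in paths.items():
        if comp.kind != "controller":
            continue
        muscle_name = paths[comp.sockets["muscle"]].name
        if comp.get("type") == "prescribed":
            out.append(PrescribedRuntime(muscle_name, ExcitationSignal(comp.get("times"), comp.get("values"))))
        else:
            out.append(
                ReflexRuntime(
                    muscle_name,
                    ReflexParams(
                        gain=comp.get("gain"), delay=comp.get("delay"),
                        velocity_threshold=comp.get("threshold"), baseline=comp.get("baseline"),
                    ),
                )
            )
    return out


def equilibrate_muscles(system: SystemSpec, state: State, excitations=0.0) -> State:
    """Set activations to the given excitations and compliant fiber lengths
    to their isometric equilibrium at the current pose."""
    st = state.copy()
    for m in system.muscles:
        u = excitations.get(m.name, 0.0) if isinstance(excitations, dict) else float(excitations)
        a = max(u, m.params.a_min)
        st.z[m.a_slot] = a
        if m.lm_slot >= 0:
            l_MT, _ = _mu.path_length_and_speed(m.path, system, st)
            st.z[m.lm_slot] = _mu.init_fiber_length(m.params, a, l_MT)
    return st


# ---------------------------------------------------------------------------
# forward integration


def _muscle_forces_and_zdot(system, state, excitations):
    """Point forces from all muscles plus the auxiliary-state derivative."""
    zdot = np.zeros(system.nz)
    point_forces = []
    for k, m in enumerate(system.muscles):
        a = float(np.clip(state.z[m.a_slot], m.params.a_min, 1.0))
        u_exc = float(np.clip(excitations[k], 0.0, 1.0))
        da = _mu.activation_derivative(u_exc, a, m.params.tau_act, m.params.tau_deact)
        if (a <= m.params.a_min and da < 0.0) or (a >= 1.0 and da > 0.0):
            da = 0.0
        zdot[m.a_slot] = da
        l_MT, v_MT = _mu.path_length_and_speed(m.path, system, state)
        if m.rigid_tendon:
            out = _mu.rigid_tendon_force(m.params, a, l_MT, v_MT)
        else:
            _, l_M_dot, out = _mu.fiber_equilibrium_and_derivative(
                m.params, a, state.z[m.lm_slot], l_MT, v_MT
            )
            zdot[m.lm_slot] = l_M_dot
        if out.force > 0.0:
            point_forces.extend(_mu.path_point_forces(m.path, system, state, out.force))
    return point_forces, zdot


def _passive_model_forces(system, state):
    """Contact and coordinate-limit forces defined by the model."""
    from .multibody import frame_kinematics

    point_forces = []
    tau = np.zeros(system.nq)
    if system.mb.contacts:
        kin = frame_kinematics(system, state)
        for c in system.mb.contacts:
            pf = contact_force(c, kin, system.mb.body_names)
            if np.any(pf.force):
                point_forces.append(pf)
    for lim in system.mb.limits:
        tau[lim.coord] += coordinate_limit_force(lim, state)
    return point_forces, tau


def _clamp_z(system, z):
    for m in system.muscles:
        z[m.a_slot] = min(max(z[m.a_slot], m.params.a_min), 1.0)
    return z


def _make_rhs(system, controllers, applied):
    nq, nz = system.nq, system.nz
    ctrl_by_muscle = {}
    for c in controllers or []:
        ctrl_by_muscle[c.muscle] = c

    def rhs(t, y):
        q = y[:nq]
        u = y[nq:2 * nq]
        z = _clamp_z(system, y[2 * nq:].copy())
        state = State(t, q, u, z)
        exc = np.zeros(len(system.muscles))
        for k, m in enumerate(system.muscles):
            c = ctrl_by_muscle.get(m.name)
            exc[k] = c.excitation(t) if c is not None else 0.0
        pf, zdot = _muscle_forces_and_zdot(system, state, exc)
        pf2, tau_passive = _passive_model_forces(system, state)
        pf.extend(pf2)
        gen = tau_passive
        if applied is not None:
            extra = applied(t, state)
            if extra is not None:
                pf.extend(extra.point_forces)
                if extra.generalized is not None:
                    gen = gen + np.asarray(extra.generalized, dtype=float)
        udot = forward_dynamics(system, state, np.zeros(nq), AppliedForces(pf, gen))
        return np.concatenate([u, udot, zdot])

    return rhs


def integrate_forward(system: SystemSpec, state0: State, t_end: float,
                      controllers=None, settings: IntegratorSettings = None,
                      t_eval=None, applied: Optional[Callable] = None) -> StatesTrajectory:
    """Integrate the model dynamics forward in time.

    The state derivative is assembled as (qdot = u; udot from forward
    dynamics under muscle, contact, limit, and user-applied forces; zdot
    from activation and fiber dynamics).  Auxiliary variables are clamped to
    their bounds.  ``applied`` is an optional callable ``(t, state) ->
    AppliedForces``.  When reflex controllers are present the integration
    proceeds in chunks no longer than a quarter of the shortest reflex delay
    and the sensed history is committed at chunk boundaries only (delay
    causality by construction).
    """
    settings = settings or IntegratorSettings()
    controllers = controllers or []
    rhs = _make_rhs(system, controllers, applied)
    y0 = np.concatenate([state0.q, state0.u, state0.z])
    t0 = state0.t

    delays = [c.delay for c in controllers if c.delay is not None]
    if delays:
        if min(delays) <= 0:
            raise ModelError("reflex delay must be > 0 for delayed simulation")
        chunk = min(min(delays) / 4.0, settings.max_step)
        max_step = chunk
    else:
        chunk = t_end - t0
        max_step = settings.max_step

    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)

    times_out, ys_out = [t0], [y0.copy()]
    for c in controllers:
        c.commit(t0, system, state0)

    tc = t0
    yc = y0
    while tc < t_end - 1e-12:
        t_next = min(tc + chunk, t_end)
        sol = solve_ivp(rhs, (tc, t_next), yc, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        max_step=max_step, dense_output=True)
        if not sol.success:
            raise SolverError(f"integrator failed near t = {sol.t[-1]:.6g} s: {sol.message}")
        if t_eval is not None:
            mask = (t_eval > tc + 1e-15) & (t_eval <= t_next + 1e-15)
            for te in t_eval[mask]:
                times_out.append(float(te))
                ys_out.append(sol.sol(te))
        else:
            for k in range(1, len(sol.t)):
                times_out.append(float(sol.t[k]))
                ys_out.append(sol.y[:, k].copy())
        yc = sol.y[:, -1].copy()
        tc = t_next
        st_end = _split_state(system, tc, yc)
        for c in controllers:
            c.commit(tc, system, st_end)

    times = np.array(times_out)
    Y = np.stack(ys_out)
    keep = np.concatenate([[True], np.diff(times) > 1e-15])
    times, Y = times[keep], Y[keep]
    nq = system.nq
    Z = Y[:, 2 * nq:]
    for i in range(Z.shape[0]):
        _clamp_z(system, Z[i])
    return StatesTrajectory(times=times, q=Y[:, :nq], u=Y[:, nq:2 * nq], z=Z)


def _split_state(system, t, y):
    nq = system.nq
    return State(t, y[:nq].copy(), y[nq:2 * nq].copy(),
                 _clamp_z(system, y[2 * nq:].copy()))


# ---------------------------------------------------------------------------
# inverse kinematics


@dataclass
class IKResult:
    table: DataTable
    rms: np.ndarray  # per-frame weighted RMS marker residual [m]
    skipped_frames: list


def solve_ik_trajectory(system: SystemSpec, marker_table: DataTable,
                        settings: IKSettings = None) -> IKResult:
    """Weighted least-squares inverse kinematics, frame by frame.

    Each frame minimizes ``sum_i w_i ||x_i_exp - x_i(q)||^2`` over the
    generalized coordinates with a damped Gauss-Newton iteration (the
    objective never increases across iterations); frames are solved in time
    order with warm starting.  Table markers that match no model marker are
    dropped with a warning; frames flagged invalid are skipped and reported.
    """
    import warnings as _warnings

    from .multibody import frame_kinematics, point_jacobian, point_kinematics

    settings = settings or IKSettings()
    tree = system.mb
    if marker_table.meta.get("Units", "m") == "mm":
        raise ModelError("marker table is in mm; convert explicitly with trc_to_meters first")

    model_markers = {m.name: m for m in tree.markers}
    used = []
    for name in marker_table.columns:
        if name in model_markers:
            used.append(model_markers[name])
        else:
            _warnings.warn(f"marker {name!r} in table matches no model marker; dropped")
    if not used:
        raise ModelError("no table markers match model markers")
    weights = np.array([
        (settings.weights or {}).get(m.name, m.weight) for m in used
    ])
    sw = np.sqrt(np.repeat(weights, 3))

    n = marker_table.nrows
    nq = system.nq
    Q = np.zeros((n, nq))
    rms = np.full(n, np.nan)
    skipped = list(marker_table.meta.get("invalid_frames", []))
    q = np.array([c.default for c in tree.coords])

    def residual_jac(q, targets):
        st = State(0.0, q, np.zeros(nq), np.zeros(0))
        kin = frame_kinematics(system, st)
        r = np.zeros(3 * len(used))
        J = np.zeros((3 * len(used), nq))
        for k, m in enumerate(used):
            x = kin.p[m.body] + kin.R[m.body] @ m.location
            r[3 * k:3 * k + 3] = x - targets[k]
            J[3 * k:3 * k + 3, :] = point_jacobian(system, kin, m.body, m.location)
        return sw * r, sw[:, None] * J

    for f in range(n):
        targets = [marker_table.columns[m.name][f] for m in used]
        if any(np.any(np.isnan(t)) for t in targets):
            if f not in skipped:
                skipped.append(f)
            Q[f] = q
            continue
        if not settings.warm_start:
            q = np.array([c.default for c in tree.coords])
        lam = 1e-8
        r, J = residual_jac(q, targets)
        cost = r @ r
        s = np.linalg.svd(J, compute_uv=False)
        if s[-1] < 1e-10 * max(s[0], 1.0):
            raise SolverError(
                f"rank-deficient marker Jacobian at frame {f} "
                f"(coordinates {[c.name for c in tree.coords]})"
            )
        for _ in range(settings.max_iter):
            g = J.T @ r
            if np.linalg.norm(g) < settings.grad_tol:
                break
            A = J.T @ J
            accepted = False
            while lam < 1e10:
                try:
                    dq = np.linalg.solve(A + lam * np.eye(nq), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                r_new, J_new = residual_jac(q + dq, targets)
                if r_new @ r_new <= cost:
                    q = q + dq
                    r, J, cost = r_new, J_new, r_new @ r_new
                    lam = max(lam / 3.0, 1e-12)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
        Q[f] = q
        rms[f] = math.sqrt((r @ r) / (3.0 * weights.sum()))
    table = DataTable(
        time=marker_table.time.copy(),
        columns={c.name: Q[:, k] for k, c in enumerate(tree.coords)},
        units={c.name: ("rad" if c.motion_type == "rotational" else "m") for c in tree.coords},
        meta={"name": "ik_coordinates", "inDegrees": False},
    )
    return IKResult(table=table, rms=rms, skipped_frames=sorted(skipped))


# ---------------------------------------------------------------------------
# inverse dynamics over a trajectory


def _fd_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """3-point central differences, 2nd-order one-sided at the ends."""
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    d[0] = (-3.0 * x[0] + 4.0 * x[1] - x[2]) / (2.0 * dt)
    d[-1] = (3.0 * x[-1] - 4.0 * x[-2] + x[-3]) / (2.0 * dt)
    return d


def solve_id_trajectory(system: SystemSpec, coord_table: DataTable,
                        external_forces_table: DataTable = None,
                        lowpass_hz: float = None,
                        allow_nonuniform: bool = False) -> DataTable:
    """Generalized forces consistent with a coordinate trajectory.

    Speeds and accelerations come from 3-point central differencing of the
    coordinate columns (optionally low-pass filtered first, zero-phase
    Butterworth at ``lowpass_hz``); each frame then runs recursive
    Newton-Euler inverse dynamics.  External generalized forces may be
    supplied as a table with columns named after coordinates; they are
    subtracted from the result.
    """
    coords = system.mb.coords
    missing = [c.name for c in coords if c.name not in coord_table.columns]
    if missing:
        raise ModelError(f"coordinate table is missing columns {missing}")
    if coord_table.meta.get("inDegrees"):
        raise ModelError("coordinate table is in degrees; convert explicitly first")
    t = coord_table.time
    if len(t) < 3:
        raise ModelError("inverse dynamics needs at least 3 frames")
    dt = float(t[-1] - t[0]) / (len(t) - 1)
    # compare against the ideal uniform grid: tolerates timestamps rounded
    # to file precision while catching genuinely non-uniform sampling
    grid_dev = np.max(np.abs(t - (t[0] + dt * np.arange(len(t)))))
    if not allow_nonuniform and grid_dev > 5e-3 * dt:
        raise ModelError("non-uniform time step; resample or pass allow_nonuniform=True")

    Q = np.stack([coord_table.columns[c.name] for c in coords], axis=1)
    if lowpass_hz is not None:
        from scipy.signal import butter, filtfilt

        b, a = butter(2, lowpass_hz * 2.0 * dt)
        Q = filtfilt(b, a, Q, axis=0)
    U = np.stack([_fd_derivative(Q[:, k], dt) for k in range(Q.shape[1])], axis=1)
    Ud = np.stack([_fd_derivative(U[:, k], dt) for k in range(U.shape[1])], axis=1)

    n = len(t)
    tau = np.zeros((n, system.nq))
    for i in range(n):
        st = State(float(t[i]), Q[i], U[i], np.zeros(0))
        applied = None
        if external_forces_table is not None:
            gen = np.zeros(system.nq)
            for k, c in enumerate(coords):
                if c.name in external_forces_table.columns:
                    gen[k] = external_forces_table.columns[c.name][i]
            applied = AppliedForces(generalized=gen)
        tau[i] = inverse_dynamics(system, st, Ud[i], applied)
    return DataTable(
        time=t.copy(),
        columns={c.name: tau[:, k] for k, c in enumerate(coords)},
        units={c.name: ("N*m" if c.motion_type == "rotational" else "N") for c in coords},
        meta={"name": "id_generalized_forces", "inDegrees": False,
              "differentiation": "central-3pt", "lowpass_hz": lowpass_hz},
    )


# ---------------------------------------------------------------------------
# static optimization


@dataclass
class SOResult:
    activations: np.ndarray  # per muscle, system order
    reserves: np.ndarray  # per coordinate
    muscle_forces: np.ndarray
    moment_arms: np.ndarray  # (n_muscles, nq)
    cost: float


def _muscle_affine_coeffs(system, state):
    """Per-muscle force = c * a + d at the current state (rigid tendon)."""
    nm = len(system.muscles)
    c = np.zeros(nm)
    d = np.zeros(nm)
    R = np.zeros((nm, system.nq))
    for k, m in enumerate(system.muscles):
        if not m.rigid_tendon:
            raise ModelError("static optimization requires rigid-tendon muscles")
        l_MT, v_MT = _mu.path_length_and_speed(m.path, system, state)
        out = _mu.rigid_tendon_force(m.params, 1.0, l_MT, v_MT)
        cos_a = math.cos(out.pennation)
        c[k] = m.params.F_max * out.f_L * out.f_V * cos_a
        d[k] = m.params.F_max * out.f_PE * cos_a
        for j in range(system.nq):
            R[k, j] = _mu.moment_arm(m.path, system, state, j)
    return c, d, R


def static_optimization_frame(system: SystemSpec, state: State, target_tau,
                              settings: SOSettings = None) -> SOResult:
    """Distribute target joint torques among muscles.

    Minimizes ``sum_i a_i^p + W sum_j rho_j^2`` subject to
    ``sum_i r_ij F_i(a_i) + rho_j = tau_j`` with ``a_i`` in [a_min, 1].
    For p = 2 the rigid-tendon force is affine in activation, so the
    reserve-eliminated problem is a bound-constrained convex least-squares
    problem solved to optimality; other exponents fall back to a
    bound-constrained quasi-Newton solve with the analytic gradient.
    """
    settings = settings or SOSettings()
    target_tau = np.asarray(target_tau, dtype=float)
    nm = len(system.muscles)
    if nm == 0:
        return SOResult(np.zeros(0), target_tau.copy(), np.zeros(0),
                        np.zeros((0, system.nq)), float(settings.reserve_penalty * target_tau @ target_tau))
    c, d, R = _muscle_affine_coeffs(system, state)
    lo = np.array([m.params.a_min for m in system.muscles])
    hi = np.ones(nm)
    W = settings.reserve_penalty
    # residual torque after passive muscle contributions
    tau_res = target_tau - R.T @ d
    G = R.T * c[None, :]  # (nq, nm): torque per unit activation

    if settings.p == 2.0:
        A = np.vstack([np.eye(nm), math.sqrt(W) * G])
        b = np.concatenate([np.zeros(nm), math.sqrt(W) * tau_res])
        res = lsq_linear(A, b, bounds=(lo, hi), tol=settings.tol, method="bvls")
        a = res.x
    else:
        from scipy.optimize import minimize

        def fg(a):
            r = tau_res - G @ a
            f = np.sum(a ** settings.p) + W * r @ r
            g = settings.p * a ** (settings.p - 1.0) - 2.0 * W * (G.T @ r)
            return f, g

        res = minimize(fg, np.clip(0.5 * np.ones(nm), lo, hi), jac=True,
                       method="L-BFGS-B", bounds=list(zip(lo, hi)),
                       options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500})
        a = np.clip(res.x, lo, hi)
    forces = c * a + d
    reserves = target_tau - R.T @ forces
    cost = float(np.sum(a ** settings.p) + W * reserves @ reserves)
    return SOResult(activations=a, reserves=reserves, muscle_forces=forces,
                    moment_arms=R, cost=cost)


# ---------------------------------------------------------------------------
# CMC-lite


def make_reference(coord_table: DataTable, system: SystemSpec):
    """Twice-differentiable reference from a coordinate table (cubic splines)."""
    coords = system.mb.coords
    missing = [c.name for c in coords if c.name not in coord_table.columns]
    if missing:
        raise ModelError(f"reference table is missing columns {missing}")
    Q = np.stack([coord_table.columns[c.name] for c in coords], axis=1)
    spline = CubicSpline(coord_table.time, Q, axis=0)
    dspline = spline.derivative()
    ddspline = dspline.derivative()
    return lambda t: (spline(t), dspline(t), ddspline(t))


def _invert_activation(params, a0: float, a_des: float, T: float) -> float:
    """Constant excitation that drives activation from a0 to a_des in time T."""
    for tau in (params.tau_act, params.tau_deact):
        e = math.exp(-T / tau)
        denom = 1.0 - e
        if denom < 1e-12:
            return min(max(a_des, 0.0), 1.0)
        u = (a_des - a0 * e) / denom
        if (tau == params.tau_act and u >= a0) or (tau == params.tau_deact and u < a0):
            return min(max(u, 0.0), 1.0)
    return min(max(u, 0.0), 1.0)


def cmc_step(system: SystemSpec, state: State, reference, t: float,
             settings: CMCSettings = None):
    """One computed-muscle-control step at time t.

    Desired accelerations combine the reference acceleration with PD
    feedback on tracking error, with the reference evaluated at the end of
    the lookahead window (t + T); inverse dynamics converts them to target
    torques (crediting the model's contact and limit forces); static
    optimization distributes the torques among muscles; and the activation
    dynamics are inverted to produce excitations that reach the desired
    activations over the lookahead window.  Returns ``(excitations dict,
    SOResult)``.
    """
    settings = settings or CMCSettings()
    q_hat, qd_hat, qdd_hat = reference(t + settings.lookahead)
    udot_star = qdd_hat + settings.kv * (qd_hat - state.u) + settings.kp * (q_hat - state.q)
    pf, tau_passive = _passive_model_forces(system, state)
    target_tau = inverse_dynamics(system, state, udot_star, AppliedForces(pf, tau_passive))
    so = static_optimization_frame(system, state, target_tau, settings.so)
    exc = {}
    for k, m in enumerate(system.muscles):
        a0 = float(np.clip(state.z[m.a_slot], m.params.a_min, 1.0))
        exc[m.name] = _invert_activation(m.params, a0, so.activations[k], settings.lookahead)
    return exc, so


class _ConstantExcitation:
    def __init__(self, muscle_name, value):
        self.muscle = muscle_name
        self.value = value
        self.delay = None

    def excitation(self, t):
        return self.value

    def commit(self, t, system, state):
        pass


def track_cmc(system: SystemSpec, state0: State, reference, t_end: float,
              settings: CMCSettings = None,
              integrator: IntegratorSettings = None) -> StatesTrajectory:
    """Closed-loop CMC-lite tracking from ``state0`` to ``t_end``.

    Excitations (and, by default, the reserve-actuator torques from static
    optimization) are recomputed every lookahead window and held constant
    within it.
    """
    settings = settings or CMCSettings()
    integrator = integrator or IntegratorSettings(rtol=1e-6, atol=1e-8)
    t = state0.t
    state = state0.copy()
    times = [t]
    qs, us, zs = [state.q.copy()], [state.u.copy()], [state.z.copy()]
    while t < t_end - 1e-12:
        T = min(settings.lookahead, t_end - t)
        exc, so = cmc_step(system, state, reference, t, settings)
        ctrls = [_ConstantExcitation(name, val) for name, val in exc.items()]
        applied = None
        if settings.apply_reserves:
            rho = so.reserves.copy()
            applied = lambda _t, _s, rho=rho: AppliedForces(generalized=rho)
        traj = integrate_forward(system, state, t + T, controllers=ctrls,
                                 settings=integrator, t_eval=[t + T], applied=applied)
        state = traj.final_state()
        t = state.t
        times.append(t)
        qs.append(state.q.copy())
        us.append(state.u.copy())
        zs.append(state.z.copy())
    return StatesTrajectory(times=np.array(times), q=np.stack(qs),
                            u=np.stack(us), z=np.stack(zs))
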
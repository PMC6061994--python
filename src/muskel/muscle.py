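"""Hill-type musculotendon actuator.

A muscle fiber (with active force-length, force-velocity, and passive
elastic properties, at a constant-width pennation angle) acts in series
with an elastic tendon along a straight-line via-point path between
skeletal attachments.  Two force modes are provided:

* rigid tendon — the tendon is inextensible at its slack length and the
  fiber state follows the path geometry algebraically;
* compliant tendon — the fiber length is a state variable whose rate comes
  from enforcing fiber-tendon force equilibrium and inverting the
  force-velocity curve.

Curve parameterizations (all dimensionless, force normalized by the maximum
isometric force F_max):

* active force-length: Gaussian ``f_L = exp(-(lm - 1)^2 / gamma)`` in
  normalized fiber length ``lm``;
* passive force-length: exponential toe, zero below optimal length and
  reaching 1 at strain ``e_0``;
* force-velocity: Hill hyperbola on the concentric side (``f_V(-1) = 0``,
  ``f_V(0) = 1``), a saturating curve with plateau ``f_ecc`` on the
  eccentric side, C1-continuous at zero velocity;
* tendon force-strain: exponential toe reaching norm force 1 at strain
  ``e_T0``, linear beyond with the matched tangent slope.

Activation dynamics are a first-order lag with separate rise and fall time
constants.  Metabolic power follows an Umberger-style partitioning into
activation/maintenance heat, shortening heat, and positive mechanical work,
plus a whole-body basal rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .components import ModelError
from .multibody import frame_kinematics, point_jacobian

__all__ = [
    "MusculotendonParams",
    "MusclePath",
    "MuscleState",
    "MuscleOutputs",
    "MetabolicCoefficients",
    "activation_derivative",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "force_velocity_inverse",
    "tendon_force_strain",
    "path_length_and_speed",
    "moment_arm",
    "rigid_tendon_force",
    "fiber_equilibrium_and_derivative",
    "init_fiber_length",
    "metabolic_rate",
]

_MIN_COS_PENNATION = 0.1  # caps pennation at 84.26 deg


@dataclass
class MusculotendonParams:
    """Hill-model constants.  Lengths in m, forces in N, times in s,
    velocities in optimal fiber lengths per second; shape factors are
    dimensionless."""

    F_max: float = 1000.0
    l_opt: float = 0.10
    l_Ts: float = 0.20
    alpha_opt: float = 0.0
    v_max: float = 10.0
    tau_act: float = 0.015
    tau_deact: float = 0.050
    gamma: float = 0.45
    k_p: float = 4.0
    e_0: float = 0.6
    e_T0: float = 0.04
    a_f: float = 0.25
    f_ecc: float = 1.4
    a_min: float = 0.01

    def __post_init__(self):
        for name in ("F_max", "l_opt", "l_Ts", "v_max", "tau_act", "tau_deact",
                     "gamma", "k_p", "e_0", "a_f", "a_min"):
            if getattr(self, name) <= 0:
                raise ModelError(f"musculotendon parameter {name} must be > 0")
        if not 0.0 <= self.alpha_opt < math.pi / 2:
            raise ModelError("alpha_opt must lie in [0, pi/2)")
        if self.f_ecc <= 1.0:
            raise ModelError("f_ecc must exceed 1")
        if not 0.0 < self.e_T0 < 0.2:
            raise ModelError("e_T0 must lie in (0, 0.2)")

    @property
    def width(self) -> float:
        """Constant pennation width h = l_opt * sin(alpha_opt) [m]."""
        return self.l_opt * math.sin(self.alpha_opt)


@dataclass
class MusclePath:
    """Ordered attachment points ``(body name, location in body frame)``."""

    points: list

    def __post_init__(self):
        if len(self.points) < 2:
            raise ModelError("a muscle path needs at least 2 points")


@dataclass
class MuscleState:
    a: float
    l_M: Optional[float] = None  # compliant mode only


@dataclass
class MuscleOutputs:
    l_MT: float
    v_MT: float
    l_T: float
    norm_fiber_length: float
    norm_fiber_velocity: float
    pennation: float
    f_L: float
    f_V: float
    f_PE: float
    f_T: float
    force: float
    fiber_length: float = 0.0
    fiber_velocity: float = 0.0
    metabolic_rate: float = 0.0
    clamped: bool = False


# ---------------------------------------------------------------------------
# characteristic curves


def activation_derivative(u: float, a: float, tau_act: float, tau_deact: float) -> float:
    """First-order activation dynamics da/dt = (u - a) / tau, with the rise
    constant when excitation exceeds activation and the fall constant
    otherwise."""
    tau = tau_act if u > a else tau_deact
    return (u - a) / tau


def active_force_length(norm_fiber_length: float, gamma: float = 0.45) -> float:
    d = norm_fiber_length - 1.0
    return math.exp(-d * d / gamma)


def passive_force_length(norm_fiber_length: float, k_p: float = 4.0, e_0: float = 0.6) -> float:
    if norm_fiber_length <= 1.0:
        return 0.0
    # exponent capped so wildly out-of-range trial lengths probed by
    # root finders and ODE steppers stay finite
    arg = min(k_p * (norm_fiber_length - 1.0) / e_0, 60.0)
    return math.expm1(arg) / math.expm1(k_p)


def _ecc_slope_gain(a_f: float, f_ecc: float) -> float:
    # eccentric curve shape factor matching the concentric slope at v = 0
    s0 = (a_f + 1.0) / a_f  # d f_V / d v at 0- of the Hill hyperbola
    return s0 / (f_ecc - 1.0)


def force_velocity(norm_fiber_velocity: float, a_f: float = 0.25, f_ecc: float = 1.4) -> float:
    v = norm_fiber_velocity
    if v <= 0.0:  # concentric (shortening): Hill hyperbola
        if v <= -1.0:
            return 0.0
        return (1.0 + v) / (1.0 - v / a_f)
    k = _ecc_slope_gain(a_f, f_ecc)
    return f_ecc - (f_ecc - 1.0) / (1.0 + k * v)


def force_velocity_inverse(f_V: float, a_f: float = 0.25, f_ecc: float = 1.4):
    """Invert the force-velocity curve.  Returns ``(v, clamped)``; targets
    outside [0, f_ecc) clamp to the corresponding velocity limit."""
    if f_V <= 0.0:
        return -1.0, f_V < 0.0
    if f_V <= 1.0:
        return (f_V - 1.0) / (1.0 + f_V / a_f), False
    k = _ecc_slope_gain(a_f, f_ecc)
    f_hi = f_ecc * (1.0 - 1e-9)
    if f_V >= f_hi:
        f_V_c = f_hi
        v = ((f_ecc - 1.0) / (f_ecc - f_V_c) - 1.0) / k
        return v, True
    return ((f_ecc - 1.0) / (f_ecc - f_V) - 1.0) / k, False


def tendon_force_strain(strain: float, e_T0: float = 0.04, k_toe: float = 3.0) -> float:
    """Normalized tendon force: 0 when slack, exponential toe reaching 1 at
    strain ``e_T0``, then linear with the matched tangent slope."""
    if strain <= 0.0:
        return 0.0
    if strain <= e_T0:
        return math.expm1(k_toe * strain / e_T0) / math.expm1(k_toe)
    slope = (k_toe / e_T0) * math.exp(k_toe) / math.expm1(k_toe)
    return 1.0 + slope * (strain - e_T0)


# ---------------------------------------------------------------------------
# path geometry


def path_length_and_speed(path, system, state):
    """Total length of the straight-segment path and its exact time
    derivative, from point positions and velocities."""
    pts = path.points if isinstance(path, MusclePath) else path
    tree = system.mb
    kin = frame_kinematics(system, state)
    xs, vs = [], []
    for body, loc in pts:
        b = tree.body_index[body] if isinstance(body, str) else body
        r = kin.R[b] @ np.asarray(loc, dtype=float)
        xs.append(kin.p[b] + r)
        vs.append(kin.v[b] + np.cross(kin.w[b], r))
    length = 0.0
    speed = 0.0
    for k in range(len(xs) - 1):
        d = xs[k + 1] - xs[k]
        seg = float(np.linalg.norm(d))
        if seg < 1e-12:
            raise ModelError(f"zero-length path segment between points {k} and {k + 1}")
        length += seg
        speed += (d @ (vs[k + 1] - vs[k])) / seg
    return length, speed


def _path_length_at_q(path, system, q):
    from .system import State  # local import to avoid a cycle

    st = State(t=0.0, q=q, u=np.zeros_like(q), z=np.zeros(0))
    length, _ = path_length_and_speed(path, system, st)
    return length


def moment_arm(path, system, state, coordinate) -> float:
    """Moment arm r = -d(l_MT)/dq by the tendon-excursion method
    (Richardson-refined central differences, base step 1e-6)."""
    if isinstance(coordinate, str):
        names = [c.name for c in system.mb.coords]
        if coordinate not in names:
            raise ModelError(f"unknown coordinate {coordinate!r}")
        coordinate = names.index(coordinate)
    q = np.asarray(state.q, dtype=float)

    def deriv(h):
        qp, qm = q.copy(), q.copy()
        qp[coordinate] += h
        qm[coordinate] -= h
        return (_path_length_at_q(path, system, qp) - _path_length_at_q(path, system, qm)) / (2.0 * h)

    h = 1e-6
    d1 = deriv(h)
    d2 = deriv(h / 2.0)
    return -(4.0 * d2 - d1) / 3.0


def path_generalized_force(path, system, state, tension: float) -> np.ndarray:
    """Generalized forces from applying ``tension`` along the path via point
    Jacobians (virtual-work route, independent of the excursion method)."""
    pts = path.points if isinstance(path, MusclePath) else path
    tree = system.mb
    kin = frame_kinematics(system, state)
    xs, bs, locs = [], [], []
    for body, loc in pts:
        b = tree.body_index[body] if isinstance(body, str) else body
        bs.append(b)
        locs.append(np.asarray(loc, dtype=float))
        xs.append(kin.p[b] + kin.R[b] @ locs[-1])
    tau = np.zeros(tree.nq)
    for k in range(len(xs)):
        F = np.zeros(3)
        if k > 0:
            d = xs[k - 1] - xs[k]
            F += tension * d / np.linalg.norm(d)
        if k < len(xs) - 1:
            d = xs[k + 1] - xs[k]
            F += tension * d / np.linalg.norm(d)
        tau += point_jacobian(system, kin, bs[k], locs[k]).T @ F
    return tau


def path_point_forces(path, system, state, tension: float):
    """Per-attachment point forces (ground frame) equivalent to a pulled
    string of the given tension routed through the via points."""
    from .multibody import PointForce

    pts = path.points if isinstance(path, MusclePath) else path
    tree = system.mb
    kin = frame_kinematics(system, state)
    xs, names, locs = [], [], []
    for body, loc in pts:
        b = tree.body_index[body] if isinstance(body, str) else body
        names.append(tree.body_names[b])
        locs.append(np.asarray(loc, dtype=float))
        xs.append(kin.p[b] + kin.R[b] @ locs[-1])
    forces = []
    for k in range(len(xs)):
        F = np.zeros(3)
        if k > 0:
            d = xs[k - 1] - xs[k]
            F += tension * d / np.linalg.norm(d)
        if k < len(xs) - 1:
            d = xs[k + 1] - xs[k]
            F += tension * d / np.linalg.norm(d)
        forces.append(PointForce(names[k], locs[k], F))
    return forces


# ---------------------------------------------------------------------------
# pennation helpers


def _pennation(params: MusculotendonParams, l_M: float):
    """(cos(alpha), alpha) for fiber length l_M under the constant-width model,
    with cos(alpha) floored at 0.1."""
    h = params.width
    if h == 0.0:
        return 1.0, 0.0
    l_M = max(l_M, h / math.sqrt(1.0 - _MIN_COS_PENNATION**2))
    sin_a = min(h / l_M, math.sqrt(1.0 - _MIN_COS_PENNATION**2))
    cos_a = math.sqrt(1.0 - sin_a * sin_a)
    return cos_a, math.asin(sin_a)


# ---------------------------------------------------------------------------
# force modes


def rigid_tendon_force(params: MusculotendonParams, a: float, l_MT: float, v_MT: float) -> MuscleOutputs:
    """Muscle force with an inextensible tendon at slack length.

    The fiber length follows from ``l_MT - l_Ts`` and the constant-width
    pennation model; the force on the skeleton is
    ``F_max (a f_L f_V + f_PE) cos(alpha)``, clamped at zero.
    """
    h = params.width
    proj = l_MT - params.l_Ts  # fiber length projected on the tendon line
    if h > 0.0:
        min_proj = h * _MIN_COS_PENNATION / math.sqrt(1.0 - _MIN_COS_PENNATION**2)
        if proj < min_proj:
            raise ModelError(
                f"geometrically impossible pennation: l_MT - l_Ts = {proj:.6g} m "
                f"is below the minimum {min_proj:.6g} m for width {h:.6g} m"
            )
        l_M = math.hypot(proj, h)
    else:
        l_M = max(proj, 1e-6 * params.l_opt)
    cos_a, alpha = _pennation(params, l_M)
    lm = l_M / params.l_opt
    l_M_dot = v_MT * cos_a
    vm = l_M_dot / (params.l_opt * params.v_max)
    f_L = active_force_length(lm, params.gamma)
    f_V = force_velocity(vm, params.a_f, params.f_ecc)
    f_PE = passive_force_length(lm, params.k_p, params.e_0)
    force = params.F_max * (a * f_L * f_V + f_PE) * cos_a
    force = max(force, 0.0)
    return MuscleOutputs(
        l_MT=l_MT, v_MT=v_MT, l_T=params.l_Ts, norm_fiber_length=lm,
        norm_fiber_velocity=vm, pennation=alpha, f_L=f_L, f_V=f_V, f_PE=f_PE,
        f_T=force / params.F_max, force=force, fiber_length=l_M,
        fiber_velocity=l_M_dot,
    )


def _equilibrium_pieces(params: MusculotendonParams, a: float, l_M: float, l_MT: float):
    cos_a, alpha = _pennation(params, l_M)
    l_T = l_MT - l_M * cos_a
    strain = l_T / params.l_Ts - 1.0
    f_T = tendon_force_strain(strain, params.e_T0)
    lm = l_M / params.l_opt
    f_L = active_force_length(lm, params.gamma)
    f_PE = passive_force_length(lm, params.k_p, params.e_0)
    return cos_a, alpha, l_T, f_T, lm, f_L, f_PE


def fiber_equilibrium_and_derivative(params: MusculotendonParams, a: float, l_M: float,
                                     l_MT: float, v_MT: float = 0.0):
    """Compliant-tendon fiber dynamics.

    Enforces the equilibrium ``f_T = (a f_L f_V + f_PE) cos(alpha)`` by
    solving for the force-velocity multiplier, inverting the force-velocity
    curve, and returning ``(residual, l_M_dot, outputs)``.  The residual is
    the normalized equilibrium defect at the returned fiber velocity (zero
    unless the velocity had to be clamped).  ``v_MT`` is accepted for
    interface symmetry with the rigid-tendon mode; the equilibrium
    formulation determines the fiber velocity from the force balance alone.
    """
    if a < params.a_min:
        a = params.a_min
    cos_a, alpha, l_T, f_T, lm, f_L, f_PE = _equilibrium_pieces(params, a, l_M, l_MT)
    f_V_target = (f_T / cos_a - f_PE) / (a * max(f_L, 1e-12))
    vm, clamped = force_velocity_inverse(f_V_target, params.a_f, params.f_ecc)
    f_V = force_velocity(vm, params.a_f, params.f_ecc)
    residual = f_T - (a * f_L * f_V + f_PE) * cos_a
    l_M_dot = vm * params.l_opt * params.v_max
    force = params.F_max * f_T
    out = MuscleOutputs(
        l_MT=l_MT, v_MT=v_MT, l_T=l_T, norm_fiber_length=lm,
        norm_fiber_velocity=vm, pennation=alpha, f_L=f_L, f_V=f_V, f_PE=f_PE,
        f_T=f_T, force=max(force, 0.0), fiber_length=l_M, fiber_velocity=l_M_dot,
        clamped=clamped,
    )
    return residual, l_M_dot, out


def init_fiber_length(params: MusculotendonParams, a: float, l_MT: float) -> float:
    """Fiber length satisfying the isometric (zero fiber velocity)
    equilibrium at the given activation, by bracketed root finding."""
    a = max(a, params.a_min)

    def g(l_M):
        cos_a, _, _, f_T, _, f_L, f_PE = _equilibrium_pieces(params, a, l_M, l_MT)
        return f_T - (a * f_L + f_PE) * cos_a

    h = params.width
    lo = max(0.05 * params.l_opt, 1.01 * h / math.sqrt(1.0 - _MIN_COS_PENNATION**2) if h else 0.0)
    hi = 2.2 * params.l_opt
    if g(lo) < 0.0 or g(hi) > 0.0:
        raise ModelError(
            f"no equilibrium bracket for fiber length with l_MT={l_MT:.6g} m, a={a:.3g}"
        )
    return brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)


# ---------------------------------------------------------------------------
# energetics


@dataclass
class MetabolicCoefficients:
    """Umberger-style heat-rate coefficients.

    activation + maintenance rates in W/kg of muscle mass; shortening-heat
    coefficient dimensionless; basal rate in W/kg of body mass.
    """

    activation: float = 40.0
    maintenance: float = 74.0
    shortening: float = 0.25
    basal: float = 1.2


def metabolic_rate(params: MusculotendonParams, outputs: MuscleOutputs, a: float,
                   muscle_mass: float, body_mass: float = 0.0,
                   coeffs: MetabolicCoefficients = MetabolicCoefficients()) -> float:
    """Metabolic power [W]: activation + maintenance heat, shortening heat,
    positive fiber mechanical work, and a basal share; never below basal."""
    if muscle_mass < 0:
        raise ModelError("muscle mass must be >= 0")
    A, M, S, B = coeffs.activation, coeffs.maintenance, coeffs.shortening, coeffs.basal
    heat = muscle_mass * (A * a + M * a * outputs.f_L)
    vm = outputs.norm_fiber_velocity
    heat += S * a * max(-vm, 0.0) * params.F_max * params.v_max * params.l_opt
    fiber_force = params.F_max * (a * outputs.f_L * outputs.f_V + outputs.f_PE)
    work = max(-fiber_force * outputs.fiber_velocity, 0.0)
    basal = B * body_mass
    return basal + max(heat + work, 0.0)
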
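"""Kinematics and dynamics of tree-structured rigid-body systems.

The skeleton is a tree of rigid bodies connected by single-degree-of-freedom
joints (pin, slider) and welds, rooted at ground.  The joint-space mass
matrix is assembled with the composite-rigid-body algorithm and bias/inverse
dynamics with a recursive Newton-Euler sweep in 6-D spatial coordinates.
Planar fixtures use the same full 3-D spatial algebra with pin axes out of
the plane; there is no special planar code path.

Angles are in radians, frames right-handed, and gravity defaults to
(0, -9.80665, 0) m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .components import GROUND_NAME, ModelError, ModelSpec
from .spatial import crf, crm, homog, homog_inv, rot, skew, spatial_inertia, xform

__all__ = [
    "BodySpec",
    "JointSpec",
    "MarkerSpec",
    "ContactSpec",
    "LimitForceSpec",
    "PointForce",
    "AppliedForces",
    "SpatialKinematics",
    "MultibodyTree",
    "compile_multibody",
    "frame_kinematics",
    "point_kinematics",
    "point_jacobian",
    "mass_matrix",
    "inverse_dynamics",
    "forward_dynamics",
    "total_energy",
    "contact_force",
    "coordinate_limit_force",
]

_JTYPE = {"root": 0, "pin": 1, "slider": 2, "weld": 3}


@dataclass
class BodySpec:
    mass: float
    com: np.ndarray
    inertia: np.ndarray  # 3x3 about the com, body coordinates


@dataclass
class JointSpec:
    jtype: str  # pin | slider | weld
    axis: np.ndarray
    parent_rotation: np.ndarray
    parent_offset: np.ndarray
    child_rotation: np.ndarray
    child_offset: np.ndarray
    coordinate: Optional[str] = None
    default: float = 0.0
    coord_range: tuple = (-np.inf, np.inf)


@dataclass
class MarkerSpec:
    name: str
    body: int  # body index in the compiled tree
    location: np.ndarray
    weight: float = 1.0


@dataclass
class ContactSpec:
    """Single-point sphere-plane spring-damper contact (Hunt-Crossley-like clamp)."""

    name: str
    body: int
    center: np.ndarray
    radius: float
    plane_point: np.ndarray
    plane_normal: np.ndarray
    stiffness: float
    dissipation: float


@dataclass
class LimitForceSpec:
    """Passive coordinate-limit element (ligament-like): stiff spring plus
    damping engaged only beyond [lower, upper]."""

    name: str
    coord: int
    lower: float
    upper: float
    stiffness: float
    damping: float


@dataclass
class PointForce:
    """A force (ground coordinates) applied at a point fixed on a body."""

    body: str
    point: np.ndarray  # in body frame [m]
    force: np.ndarray  # in ground frame [N]


@dataclass
class AppliedForces:
    point_forces: list = field(default_factory=list)
    generalized: Optional[np.ndarray] = None  # length nu


@dataclass
class CoordinateInfo:
    name: str
    joint: str
    motion_type: str  # rotational | translational
    default: float
    coord_range: tuple
    body: int  # index of the child body it moves


@dataclass
class SpatialKinematics:
    """Per-body ground-frame pose and velocity, plus joint geometry in ground."""

    R: np.ndarray  # (nb, 3, 3) body -> ground rotations
    p: np.ndarray  # (nb, 3) body origin positions
    w: np.ndarray  # (nb, 3) angular velocities
    v: np.ndarray  # (nb, 3) body-origin linear velocities
    vs: np.ndarray  # (nb, 6) spatial velocities in body coordinates
    joint_origin: np.ndarray  # (nb, 3) joint-frame origin in ground
    joint_axis: np.ndarray  # (nb, 3) joint axis in ground


@dataclass
class MultibodyTree:
    """Compiled, immutable description of the body-joint tree."""

    body_names: list
    parent: list  # parent body index (-1 for ground)
    bodies: list  # BodySpec per body (ground has zero mass)
    joints: list  # JointSpec per body (None for ground)
    joint_names: list
    jtype: np.ndarray  # int codes per body
    axis: np.ndarray  # (nb, 3)
    X1: list  # parent-body coords -> parent joint frame (6x6)
    X2: list  # child joint frame -> child-body coords (6x6)
    T1: list  # parent joint frame -> parent-body coords (4x4)
    T2i: list  # child-body coords -> child joint frame, inverted (4x4)
    S: list  # motion subspace in child-body coords (6,) or None
    coord_of_body: np.ndarray  # coordinate index per body, -1 if none
    coords: list  # CoordinateInfo, tree preorder
    coord_chain: list  # per body: list of (coord index, body index) from root
    I6: list  # spatial inertia per body
    markers: list  # MarkerSpec
    contacts: list  # ContactSpec
    limits: list  # LimitForceSpec
    body_index: dict  # name -> index

    @property
    def nb(self) -> int:
        return len(self.body_names)

    @property
    def nq(self) -> int:
        return len(self.coords)


def compile_multibody(model: ModelSpec) -> MultibodyTree:
    """Flatten a validated model into arrays ordered by joint-tree preorder."""
    paths = dict(model.walk())
    body_paths = [p for p, c in paths.items() if c.kind == "body"]
    joint_items = [(p, c) for p, c in paths.items() if c.kind == "joint"]

    ground = next(p for p in body_paths if paths[p].name == GROUND_NAME)
    children = {bp: [] for bp in body_paths}
    for jp, jc in joint_items:
        children[jc.sockets["parent_body"]].append((jp, jc))

    body_names, parent, bodies, joints, joint_names = [], [], [], [], []
    order_of = {}

    def _add_body(bp, parent_idx, joint_path, joint_comp):
        idx = len(body_names)
        comp = paths[bp]
        order_of[bp] = idx
        body_names.append(comp.name)
        parent.append(parent_idx)
        bodies.append(
            BodySpec(comp.get("mass"), np.asarray(comp.get("com")), np.asarray(comp.get("inertia")))
        )
        if joint_comp is None:
            joints.append(None)
            joint_names.append(None)
        else:
            jt = joint_comp.get("type")
            joints.append(
                JointSpec(
                    jtype=jt,
                    axis=np.asarray(joint_comp.get("axis")),
                    parent_rotation=np.asarray(joint_comp.get("parent_rotation")),
                    parent_offset=np.asarray(joint_comp.get("parent_offset")),
                    child_rotation=np.asarray(joint_comp.get("child_rotation")),
                    child_offset=np.asarray(joint_comp.get("child_offset")),
                    coordinate=None if jt == "weld" else joint_comp.name,
                    default=joint_comp.get("default", 0.0),
                    coord_range=tuple(joint_comp.get("range", (-np.inf, np.inf))),
                )
            )
            joint_names.append(joint_comp.name)
        for cjp, cjc in children[bp]:  # preorder, declaration order
            _add_body(cjc.sockets["child_body"], idx, cjp, cjc)

    _add_body(ground, -1, None, None)

    nb = len(body_names)
    jtype = np.zeros(nb, dtype=int)
    axis = np.zeros((nb, 3))
    X1, X2, T1, T2i, S = [None] * nb, [None] * nb, [None] * nb, [None] * nb, [None] * nb
    coord_of_body = -np.ones(nb, dtype=int)
    coords = []
    for i in range(1, nb):
        j = joints[i]
        jtype[i] = _JTYPE[j.jtype]
        axis[i] = j.axis
        X1[i] = xform(j.parent_rotation.T, j.parent_offset)
        X2[i] = xform(j.child_rotation, -j.child_rotation.T @ j.child_offset)
        T1[i] = homog(j.parent_rotation, j.parent_offset)
        T2i[i] = homog_inv(homog(j.child_rotation, j.child_offset))
        if j.jtype == "pin":
            S[i] = X2[i] @ np.concatenate([j.axis, np.zeros(3)])
        elif j.jtype == "slider":
            S[i] = X2[i] @ np.concatenate([np.zeros(3), j.axis])
        if j.jtype != "weld":
            coord_of_body[i] = len(coords)
            coords.append(
                CoordinateInfo(
                    name=j.coordinate,
                    joint=joint_names[i],
                    motion_type="rotational" if j.jtype == "pin" else "translational",
                    default=j.default,
                    coord_range=j.coord_range,
                    body=i,
                )
            )

    coord_chain = [[] for _ in range(nb)]
    for i in range(1, nb):
        chain = list(coord_chain[parent[i]])
        if coord_of_body[i] >= 0:
            chain.append((coord_of_body[i], i))
        coord_chain[i] = chain

    I6 = [spatial_inertia(b.mass, b.com, b.inertia) for b in bodies]
    body_index = {bp_name: i for i, bp_name in enumerate(body_names)}

    markers = [
        MarkerSpec(c.name, order_of[c.sockets["parent_body"]], np.asarray(c.get("location")), c.get("weight"))
        for p, c in paths.items()
        if c.kind == "marker"
    ]
    contacts = [
        ContactSpec(
            c.name,
            order_of[c.sockets["body"]],
            np.asarray(c.get("center")),
            c.get("radius"),
            np.asarray(c.get("plane_point")),
            np.asarray(c.get("plane_normal")),
            c.get("stiffness"),
            c.get("dissipation"),
        )
        for p, c in paths.items()
        if c.kind == "contact"
    ]
    coord_index = {ci.name: k for k, ci in enumerate(coords)}
    limits = []
    for p, c in paths.items():
        if c.kind != "coordinate_limit_force":
            continue
        jname = paths[c.sockets["joint"]].name
        if jname not in coord_index:
            raise ModelError(f"limit force {p!r} targets joint {jname!r} which has no coordinate")
        limits.append(
            LimitForceSpec(c.name, coord_index[jname], c.get("lower"), c.get("upper"),
                           c.get("stiffness"), c.get("damping"))
        )

    return MultibodyTree(
        body_names=body_names, parent=parent, bodies=bodies, joints=joints,
        joint_names=joint_names, jtype=jtype, axis=axis, X1=X1, X2=X2, T1=T1, T2i=T2i,
        S=S, coord_of_body=coord_of_body, coords=coords, coord_chain=coord_chain,
        I6=I6, markers=markers, contacts=contacts, limits=limits, body_index=body_index,
    )


# ---------------------------------------------------------------------------
# per-state joint transforms


def _joint_transforms(tree: MultibodyTree, q: np.ndarray):
    """Per-body (Xup, TJ) at configuration q."""
    Xup = [None] * tree.nb
    T = [None] * tree.nb
    for i in range(1, tree.nb):
        jt = tree.jtype[i]
        qi = q[tree.coord_of_body[i]] if tree.coord_of_body[i] >= 0 else 0.0
        if jt == _JTYPE["pin"]:
            Rj = rot(tree.axis[i], qi)
            XJ = xform(Rj.T, np.zeros(3))
            TJ = homog(Rj, np.zeros(3))
        elif jt == _JTYPE["slider"]:
            XJ = xform(np.eye(3), qi * tree.axis[i])
            TJ = homog(np.eye(3), qi * tree.axis[i])
        else:  # weld
            XJ = np.eye(6)
            TJ = np.eye(4)
        Xup[i] = tree.X2[i] @ XJ @ tree.X1[i]
        T[i] = TJ
    return Xup, T


def frame_kinematics(system, state) -> SpatialKinematics:
    """Ground-frame pose and velocity of every body, by preorder traversal.

    Results are cached on the system keyed by (q, u) when the system's cache
    is enabled; cached and uncached results are bitwise identical because the
    cache stores the full result object of the same computation.
    """
    cache = getattr(system, "_kin_cache", None)
    key = None
    if cache is not None and system.cache_enabled:
        key = (state.q.tobytes(), state.u.tobytes())
        hit = cache.get(key)
        if hit is not None:
            return hit
    tree = system.mb
    kin = _frame_kinematics_raw(tree, state.q, state.u)
    if key is not None:
        cache.clear()  # keep at most one entry; invalidates on q/u change
        cache[key] = kin
    return kin


def _frame_kinematics_raw(tree: MultibodyTree, q: np.ndarray, u: np.ndarray) -> SpatialKinematics:
    nb = tree.nb
    Xup, TJ = _joint_transforms(tree, q)
    Tg = [np.eye(4)] + [None] * (nb - 1)
    vs = np.zeros((nb, 6))
    joint_origin = np.zeros((nb, 3))
    joint_axis = np.zeros((nb, 3))
    for i in range(1, nb):
        p = tree.parent[i]
        Tjp = Tg[p] @ tree.T1[i]  # parent joint frame in ground
        Tg[i] = Tjp @ TJ[i] @ tree.T2i[i]
        joint_origin[i] = Tjp[:3, 3]
        joint_axis[i] = Tjp[:3, :3] @ tree.axis[i]
        vi = Xup[i] @ vs[p]
        ci = tree.coord_of_body[i]
        if ci >= 0:
            vi = vi + tree.S[i] * u[ci]
        vs[i] = vi
    R = np.stack([T[:3, :3] for T in Tg])
    p_ = np.stack([T[:3, 3] for T in Tg])
    w = np.einsum("nij,nj->ni", R, vs[:, :3])
    v = np.einsum("nij,nj->ni", R, vs[:, 3:])
    return SpatialKinematics(R=R, p=p_, w=w, v=v, vs=vs,
                             joint_origin=joint_origin, joint_axis=joint_axis)


def point_kinematics(system, state, body, point_in_body):
    """Ground-frame position and velocity of a point fixed on ``body``."""
    tree = system.mb
    if isinstance(body, str):
        if body not in tree.body_index:
            raise ModelError(f"unknown body {body!r}")
        body = tree.body_index[body]
    kin = frame_kinematics(system, state)
    pt = np.asarray(point_in_body, dtype=float)
    r = kin.R[body] @ pt
    x = kin.p[body] + r
    xdot = kin.v[body] + np.cross(kin.w[body], r)
    return x, xdot


def point_jacobian(system, kin: SpatialKinematics, body: int, point_in_body) -> np.ndarray:
    """3 x nq Jacobian of the ground-frame position of a body-fixed point."""
    tree = system.mb
    x = kin.p[body] + kin.R[body] @ np.asarray(point_in_body, dtype=float)
    J = np.zeros((3, tree.nq))
    for ci, bi in tree.coord_chain[body]:
        if tree.jtype[bi] == _JTYPE["pin"]:
            J[:, ci] = np.cross(kin.joint_axis[bi], x - kin.joint_origin[bi])
        else:  # slider
            J[:, ci] = kin.joint_axis[bi]
    return J


# ---------------------------------------------------------------------------
# dynamics


def _external_to_body_forces(tree: MultibodyTree, kin: SpatialKinematics, applied):
    """Convert applied point forces to spatial forces in body coordinates."""
    fext = np.zeros((tree.nb, 6))
    if applied is None:
        return fext, None
    for pf in applied.point_forces:
        b = tree.body_index[pf.body] if isinstance(pf.body, str) else pf.body
        F = np.asarray(pf.force, dtype=float)
        r = kin.R[b] @ np.asarray(pf.point, dtype=float)
        n_g = np.cross(r, F)  # moment about body origin, ground coords
        fext[b, :3] += kin.R[b].T @ n_g
        fext[b, 3:] += kin.R[b].T @ F
    return fext, applied.generalized


def _rnea(tree: MultibodyTree, gravity, q, u, udot, fext=None):
    """Recursive Newton-Euler: tau = M(q) udot + bias(q, u) - fext contribution."""
    nb = tree.nb
    Xup, _ = _joint_transforms(tree, q)
    v = np.zeros((nb, 6))
    a = np.zeros((nb, 6))
    a[0, 3:] = -np.asarray(gravity, dtype=float)
    f = np.zeros((nb, 6))
    for i in range(1, nb):
        p = tree.parent[i]
        ci = tree.coord_of_body[i]
        vi = Xup[i] @ v[p]
        ai = Xup[i] @ a[p]
        if ci >= 0:
            Su = tree.S[i] * u[ci]
            vi = vi + Su
            ai = ai + tree.S[i] * udot[ci] + crm(vi) @ Su
        v[i] = vi
        a[i] = ai
        f[i] = tree.I6[i] @ ai + crf(vi) @ (tree.I6[i] @ vi)
    if fext is not None:
        f[1:] -= fext[1:]
    tau = np.zeros(tree.nq)
    for i in range(nb - 1, 0, -1):
        ci = tree.coord_of_body[i]
        if ci >= 0:
            tau[ci] = tree.S[i] @ f[i]
        f[tree.parent[i]] += Xup[i].T @ f[i]
    return tau


def mass_matrix(system, state) -> np.ndarray:
    """Joint-space mass matrix M(q) by the composite-rigid-body algorithm."""
    tree = system.mb
    Xup, _ = _joint_transforms(tree, state.q)
    Ic = [I.copy() for I in tree.I6]
    H = np.zeros((tree.nq, tree.nq))
    for i in range(tree.nb - 1, 0, -1):
        p = tree.parent[i]
        Ic[p] += Xup[i].T @ Ic[i] @ Xup[i]
        ci = tree.coord_of_body[i]
        if ci < 0:
            continue
        F = Ic[i] @ tree.S[i]
        H[ci, ci] = tree.S[i] @ F
        j = i
        while tree.parent[j] > 0:
            F = Xup[j].T @ F
            j = tree.parent[j]
            cj = tree.coord_of_body[j]
            if cj >= 0:
                H[ci, cj] = H[cj, ci] = tree.S[j] @ F
    return H


def inverse_dynamics(system, state, udot, applied_forces: Optional[AppliedForces] = None) -> np.ndarray:
    """Generalized forces tau satisfying M udot + bias(q, u) - applied = tau."""
    tree = system.mb
    udot = np.asarray(udot, dtype=float)
    if udot.shape != (tree.nq,):
        raise ModelError(f"udot must have length {tree.nq}, got shape {udot.shape}")
    kin = frame_kinematics(system, state)
    fext, gen = _external_to_body_forces(tree, kin, applied_forces)
    tau = _rnea(tree, system.gravity, state.q, state.u, udot, fext)
    if gen is not None:
        tau = tau - np.asarray(gen, dtype=float)
    return tau


def forward_dynamics(system, state, tau, applied_forces: Optional[AppliedForces] = None) -> np.ndarray:
    """Accelerations udot solving M udot = tau + applied - bias."""
    tree = system.mb
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (tree.nq,):
        raise ModelError(f"tau must have length {tree.nq}, got shape {tau.shape}")
    kin = frame_kinematics(system, state)
    fext, gen = _external_to_body_forces(tree, kin, applied_forces)
    bias = _rnea(tree, system.gravity, state.q, state.u, np.zeros(tree.nq), fext)
    if gen is not None:
        bias = bias - np.asarray(gen, dtype=float)
    H = mass_matrix(system, state)
    try:
        c, low = scipy.linalg.cho_factor(H)
    except np.linalg.LinAlgError as exc:
        raise ModelError("mass matrix is singular (zero-mass chain?)") from exc
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - scipy alias
        raise ModelError("mass matrix is singular (zero-mass chain?)") from exc
    return scipy.linalg.cho_solve((c, low), tau - bias)


def total_energy(system, state) -> float:
    """Kinetic plus gravitational potential energy [J].

    The potential-energy datum is the ground-origin plane normal to gravity.
    """
    tree = system.mb
    kin = frame_kinematics(system, state)
    ke = 0.0
    pe = 0.0
    g = np.asarray(system.gravity, dtype=float)
    for i in range(1, tree.nb):
        ke += 0.5 * kin.vs[i] @ tree.I6[i] @ kin.vs[i]
        com_g = kin.p[i] + kin.R[i] @ tree.bodies[i].com
        pe -= tree.bodies[i].mass * (g @ com_g)
    return ke + pe


# ---------------------------------------------------------------------------
# passive force elements


def contact_force(contact: ContactSpec, kin: SpatialKinematics, body_names=None) -> PointForce:
    """Sphere-plane contact force: f = k * delta * (1 + c * delta_dot), clamped >= 0.

    Returns a zero-force :class:`PointForce` when the sphere does not
    penetrate the plane.  The normal force is never adhesive.
    """
    b = contact.body
    r_c = kin.R[b] @ contact.center
    x = kin.p[b] + r_c
    xdot = kin.v[b] + np.cross(kin.w[b], r_c)
    n = contact.plane_normal
    dist = (x - contact.plane_point) @ n
    delta = contact.radius - dist
    name = body_names[b] if body_names is not None else b
    if delta <= 0.0:
        return PointForce(name, contact.center.copy(), np.zeros(3))
    delta_dot = -(n @ xdot)
    fmag = contact.stiffness * delta * (1.0 + contact.dissipation * delta_dot)
    fmag = max(fmag, 0.0)
    cp_ground = x - n * dist
    cp_body = kin.R[b].T @ (cp_ground - kin.p[b])
    return PointForce(name, cp_body, fmag * n)


def coordinate_limit_force(limit: LimitForceSpec, state) -> float:
    """Generalized restoring force, zero inside [lower, upper] and spring +
    damper beyond; continuous in q at the limits."""
    q = state.q[limit.coord]
    u = state.u[limit.coord]
    if q > limit.upper:
        return -limit.stiffness * (q - limit.upper) - limit.damping * u
    if q < limit.lower:
        return -limit.stiffness * (q - limit.lower) - limit.damping * u
    return 0.0
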
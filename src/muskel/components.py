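"""Component-based model descriptions.

A model is an ordered tree of components (bodies, joints, muscles, markers,
controllers, contact elements, coordinate-limit forces, reporters).  Each
component carries typed properties with units, sockets that bind it to other
components by path, and optional input connections that receive another
component's output signal.  The model is a pure description: compiling it to
an executable system of equations lives in :mod:`muskel.system`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

KINDS = (
    "body",
    "joint",
    "muscle",
    "marker",
    "controller",
    "contact",
    "coordinate_limit_force",
    "reporter",
)

GROUND_NAME = "ground"
DEFAULT_GRAVITY = np.array([0.0, -9.80665, 0.0])

#: socket name -> required target kind, per component kind
SOCKET_SCHEMA = {
    "joint": {"parent_body": "body", "child_body": "body"},
    "marker": {"parent_body": "body"},
    "contact": {"body": "body"},
    "coordinate_limit_force": {"joint": "joint"},
    "controller": {"muscle": "muscle"},
}

#: output signal name -> (type, units), per component kind
OUTPUT_SIGNALS = {
    "joint": {"q": ("scalar", "rad"), "u": ("scalar", "rad/s")},
    "muscle": {
        "path_length": ("scalar", "m"),
        "path_speed": ("scalar", "m/s"),
        "fiber_length": ("scalar", "m"),
        "norm_fiber_length": ("scalar", "1"),
        "fiber_velocity_norm": ("scalar", "1"),
        "tendon_length": ("scalar", "m"),
        "pennation": ("scalar", "rad"),
        "activation": ("scalar", "1"),
        "force": ("scalar", "N"),
        "f_L": ("scalar", "1"),
        "f_V": ("scalar", "1"),
        "f_PE": ("scalar", "1"),
        "f_T": ("scalar", "1"),
        "metabolic_rate": ("scalar", "W"),
    },
    "marker": {"position": ("vec3", "m")},
    "controller": {"excitation": ("scalar", "1")},
    "body": {},
    "contact": {},
    "coordinate_limit_force": {},
    "reporter": {},
}

#: declared input slots: name -> expected signal type; reporters accept any name
INPUT_SLOTS = {
    "controller": {"signal": "scalar"},
}

#: inputs whose effect passes through dynamics (delayed sensing); these edges
#: do not participate in the non-dynamic-cycle check.
DYNAMIC_INPUTS = {("controller", "signal")}


class ModelError(ValueError):
    """Raised for invalid model descriptions (bad wiring, broken invariants)."""


@dataclass
class Property:
    """A typed property value with units.

    Supported value types: float, bool, str, 3-vector, 3x3 matrix, 1-D float
    array, and lists of path points ``(body_path, 3-vector)``.
    """

    value: object
    units: str = ""


@dataclass
class ComponentSpec:
    name: str
    kind: str
    properties: dict = field(default_factory=dict)
    sockets: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    children: list = field(default_factory=list)

    def get(self, prop: str, default=None):
        if prop in self.properties:
            return self.properties[prop].value
        return default

    def set(self, prop: str, value, units: str = "") -> None:
        self.properties[prop] = Property(value, units)


@dataclass
class ModelSpec:
    name: str
    gravity: np.ndarray = field(default_factory=lambda: DEFAULT_GRAVITY.copy())
    components: list = field(default_factory=list)

    # -- tree navigation -------------------------------------------------
    def walk(self) -> Iterator[tuple[str, ComponentSpec]]:
        """Yield ``(path, component)`` pairs in depth-first preorder."""

        def _walk(prefix, comps):
            for c in comps:
                path = f"{prefix}/{c.name}"
                yield path, c
                yield from _walk(path, c.children)

        yield from _walk("", self.components)

    def find(self, path: str) -> Optional[ComponentSpec]:
        for p, c in self.walk():
            if p == path:
                return c
        return None

    def path_of(self, comp: ComponentSpec) -> str:
        for p, c in self.walk():
            if c is comp:
                return p
        raise ModelError(f"component {comp.name!r} is not in model {self.name!r}")

    def add(self, comp: ComponentSpec) -> ComponentSpec:
        self.components.append(comp)
        return comp


# ---------------------------------------------------------------------------
# factories


def make_body(name, mass, com=(0.0, 0.0, 0.0), inertia=None) -> ComponentSpec:
    c = ComponentSpec(name, "body")
    c.set("mass", float(mass), "kg")
    c.set("com", np.asarray(com, dtype=float), "m")
    if inertia is None:
        inertia = np.zeros((3, 3))
    inertia = np.asarray(inertia, dtype=float)
    if inertia.shape == (3,):
        inertia = np.diag(inertia)
    c.set("inertia", inertia, "kg*m^2")
    return c


def make_ground() -> ComponentSpec:
    return make_body(GROUND_NAME, 0.0)


def make_joint(
    name,
    joint_type,
    parent_body,
    child_body,
    axis=(0.0, 0.0, 1.0),
    parent_offset=(0.0, 0.0, 0.0),
    parent_rotation=None,
    child_offset=(0.0, 0.0, 0.0),
    child_rotation=None,
    default=0.0,
    coord_range=(-2.0 * math.pi, 2.0 * math.pi),
) -> ComponentSpec:
    """A pin, slider, or weld joint connecting two body frames."""
    if joint_type not in ("pin", "slider", "weld"):
        raise ModelError(f"unknown joint type {joint_type!r}")
    angular = joint_type == "pin"
    c = ComponentSpec(name, "joint")
    c.sockets["parent_body"] = parent_body
    c.sockets["child_body"] = child_body
    c.set("type", joint_type)
    c.set("axis", np.asarray(axis, dtype=float), "1")
    c.set("parent_offset", np.asarray(parent_offset, dtype=float), "m")
    c.set("parent_rotation", np.asarray(parent_rotation if parent_rotation is not None else np.eye(3), dtype=float), "1")
    c.set("child_offset", np.asarray(child_offset, dtype=float), "m")
    c.set("child_rotation", np.asarray(child_rotation if child_rotation is not None else np.eye(3), dtype=float), "1")
    if joint_type != "weld":
        c.set("default", float(default), "rad" if angular else "m")
        c.set("range", np.asarray(coord_range, dtype=float), "rad" if angular else "m")
    return c


def make_marker(name, parent_body, location, weight=1.0) -> ComponentSpec:
    c = ComponentSpec(name, "marker")
    c.sockets["parent_body"] = parent_body
    c.set("location", np.asarray(location, dtype=float), "m")
    c.set("weight", float(weight), "1")
    return c


def make_muscle(name, path_points, params=None, rigid_tendon=True) -> ComponentSpec:
    """Hill-type musculotendon actuator routed through straight-line via points.

    ``path_points`` is an ordered list of ``(body_path, location)`` pairs;
    ``params`` is a mapping of musculotendon parameter overrides (see
    :class:`muskel.muscle.MusculotendonParams` for names and defaults).
    """
    c = ComponentSpec(name, "muscle")
    pts = [(bp, np.asarray(loc, dtype=float)) for bp, loc in path_points]
    c.set("path", pts, "m")
    c.set("rigid_tendon", bool(rigid_tendon))
    for key, val in (params or {}).items():
        c.set(key, float(val))
    return c


def make_contact(name, body, center, radius, plane_point=(0, 0, 0),
                 plane_normal=(0.0, 1.0, 0.0), stiffness=1e5, dissipation=1.0) -> ComponentSpec:
    c = ComponentSpec(name, "contact")
    c.sockets["body"] = body
    c.set("center", np.asarray(center, dtype=float), "m")
    c.set("radius", float(radius), "m")
    c.set("plane_point", np.asarray(plane_point, dtype=float), "m")
    c.set("plane_normal", np.asarray(plane_normal, dtype=float), "1")
    c.set("stiffness", float(stiffness), "N/m")
    c.set("dissipation", float(dissipation), "s/m")
    return c


def make_limit_force(name, joint, lower, upper, stiffness, damping) -> ComponentSpec:
    c = ComponentSpec(name, "coordinate_limit_force")
    c.sockets["joint"] = joint
    c.set("lower", float(lower), "rad")
    c.set("upper", float(upper), "rad")
    c.set("stiffness", float(stiffness), "N*m/rad")
    c.set("damping", float(damping), "N*m*s/rad")
    return c


def make_prescribed_controller(name, muscle, times, values) -> ComponentSpec:
    c = ComponentSpec(name, "controller")
    c.sockets["muscle"] = muscle
    c.set("type", "prescribed")
    c.set("times", np.asarray(times, dtype=float), "s")
    c.set("values", np.asarray(values, dtype=float), "1")
    return c


def make_reflex_controller(name, muscle, gain, delay, threshold=0.0, baseline=0.0) -> ComponentSpec:
    c = ComponentSpec(name, "controller")
    c.sockets["muscle"] = muscle
    c.set("type", "reflex")
    c.set("gain", float(gain), "1")
    c.set("delay", float(delay), "s")
    c.set("threshold", float(threshold), "1")
    c.set("baseline", float(baseline), "1")
    return c


def make_reporter(name, inputs=None) -> ComponentSpec:
    c = ComponentSpec(name, "reporter")
    for label, source in (inputs or {}).items():
        c.inputs[label] = source
    return c


# ---------------------------------------------------------------------------
# validation


def _is_psd_with_triangle(I: np.ndarray, tol=1e-9) -> bool:
    if not np.allclose(I, I.T, atol=1e-12):
        return False
    lam = np.sort(np.linalg.eigvalsh(I))
    if lam[0] < -tol:
        return False
    # triangle inequalities on principal moments
    return (lam[0] + lam[1] >= lam[2] - tol)


def resolve_output(model: ModelSpec, ref: str):
    """Resolve ``'component_path:output_name'`` to ``(path, comp, name, type, units)``."""
    if ":" not in ref:
        raise ModelError(f"output reference {ref!r} must have the form 'path:output'")
    path, out = ref.rsplit(":", 1)
    comp = model.find(path)
    if comp is None:
        raise ModelError(f"output reference {ref!r}: no component at {path!r}")
    avail = OUTPUT_SIGNALS.get(comp.kind, {})
    if out not in avail:
        raise ModelError(
            f"component {path!r} (kind {comp.kind!r}) has no output {out!r}; "
            f"available: {sorted(avail)}"
        )
    sig_type, units = avail[out]
    return path, comp, out, sig_type, units


def connect_io(model: ModelSpec, output_path: str, input_path: str) -> ModelSpec:
    """Wire a component output to another component's input.

    ``output_path`` is ``'source_component:output_name'`` and ``input_path``
    is ``'target_component:input_name'``.  Signal types must match; the
    wiring is recorded on the target component and honoured by the
    evaluation order that :func:`muskel.system.build_system` computes.
    """
    _, _, _, sig_type, _ = resolve_output(model, output_path)
    if ":" not in input_path:
        raise ModelError(f"input reference {input_path!r} must have the form 'path:input'")
    tpath, iname = input_path.rsplit(":", 1)
    target = model.find(tpath)
    if target is None:
        raise ModelError(f"input reference {input_path!r}: no component at {tpath!r}")
    slots = INPUT_SLOTS.get(target.kind)
    if target.kind == "reporter":
        expected = None  # reporters accept any signal under any label
    elif slots is None or iname not in slots:
        raise ModelError(
            f"component {tpath!r} (kind {target.kind!r}) has no input {iname!r}"
        )
    else:
        expected = slots[iname]
    if expected is not None and expected != sig_type:
        raise ModelError(
            f"signal type mismatch wiring {output_path!r} -> {input_path!r}: "
            f"{sig_type} vs expected {expected}"
        )
    src_path = output_path.rsplit(":", 1)[0]
    if src_path == tpath:
        raise ModelError(f"component {tpath!r} cannot connect an input to itself")
    target.inputs[iname] = output_path
    return model


def validate_model(model: ModelSpec) -> None:
    """Check every model invariant; raise :class:`ModelError` on the first failure."""
    # sibling name uniqueness
    def _check_siblings(comps, where):
        seen = {}
        for c in comps:
            if c.kind not in KINDS:
                raise ModelError(f"unknown component kind {c.kind!r} for {c.name!r}")
            if c.name in seen:
                raise ModelError(
                    f"duplicate sibling names {c.name!r} under {where or '/'} "
                    f"(kinds {seen[c.name].kind!r} and {c.kind!r})"
                )
            seen[c.name] = c
            _check_siblings(c.children, f"{where}/{c.name}")

    _check_siblings(model.components, "")

    paths = dict(model.walk())

    # sockets resolve to existing components of the required kind
    for path, comp in paths.items():
        schema = SOCKET_SCHEMA.get(comp.kind, {})
        for sname, required_kind in schema.items():
            if sname not in comp.sockets:
                raise ModelError(f"component {path!r} is missing socket {sname!r}")
        for sname, target in comp.sockets.items():
            if sname not in schema:
                raise ModelError(f"component {path!r} has unknown socket {sname!r}")
            tgt = paths.get(target)
            if tgt is None:
                raise ModelError(
                    f"socket {sname!r} of component {path!r} does not resolve: "
                    f"no component at {target!r}"
                )
            if tgt.kind != schema[sname]:
                raise ModelError(
                    f"socket {sname!r} of component {path!r} must target a "
                    f"{schema[sname]!r}, found {tgt.kind!r} at {target!r}"
                )

    # input wiring: no self-connection, sources resolve
    for path, comp in paths.items():
        for iname, src in comp.inputs.items():
            _, _, _, _, _ = resolve_output(model, src)
            if src.rsplit(":", 1)[0] == path:
                raise ModelError(f"component {path!r} input {iname!r} connects to itself")

    # exactly one ground body
    grounds = [p for p, c in paths.items() if c.kind == "body" and c.name == GROUND_NAME]
    if len(grounds) != 1:
        raise ModelError(
            f"model must contain exactly one ground body named {GROUND_NAME!r}; found {len(grounds)}"
        )

    # body-joint graph is a tree rooted at ground
    bodies = {p for p, c in paths.items() if c.kind == "body"}
    parent_of = {}
    for path, comp in paths.items():
        if comp.kind != "joint":
            continue
        child = comp.sockets["child_body"]
        if paths[child].name == GROUND_NAME:
            raise ModelError(f"joint {path!r} uses ground as its child body")
        if child in parent_of:
            raise ModelError(
                f"body {child!r} is the child of two joints "
                f"({parent_of[child][0]!r} and {path!r}); kinematic loops unsupported"
            )
        parent_of[child] = (path, comp.sockets["parent_body"])
    for b in bodies:
        if paths[b].name == GROUND_NAME:
            continue
        if b not in parent_of:
            raise ModelError(f"body {b!r} is not connected to the tree by any joint")
        # walk to ground, detecting cycles
        seen = {b}
        cur = b
        while paths[cur].name != GROUND_NAME:
            if cur not in parent_of:
                raise ModelError(f"body {cur!r} is not connected to ground")
            cur = parent_of[cur][1]
            if cur in seen:
                raise ModelError(f"cycle in body-joint graph at {cur!r}: kinematic loops unsupported")
            seen.add(cur)

    _validate_typed_properties(model, paths)


def _validate_typed_properties(model, paths):
    g = np.asarray(model.gravity, dtype=float)
    if g.shape != (3,) or not np.all(np.isfinite(g)):
        raise ModelError("gravity must be a finite 3-vector")
    for path, comp in paths.items():
        k = comp.kind
        if k == "body":
            m = comp.get("mass")
            if m is None or m < 0:
                raise ModelError(f"body {path!r} has negative or missing mass")
            I = np.asarray(comp.get("inertia"))
            if not _is_psd_with_triangle(I):
                raise ModelError(
                    f"body {path!r} inertia must be symmetric PSD with valid principal moments"
                )
        elif k == "joint":
            jt = comp.get("type")
            if jt not in ("pin", "slider", "weld"):
                raise ModelError(f"joint {path!r} has unknown type {jt!r}")
            axis = np.asarray(comp.get("axis"))
            if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
                raise ModelError(f"joint {path!r} axis must be a unit vector")
            if jt != "weld":
                lo, hi = comp.get("range")
                if not lo < hi:
                    raise ModelError(f"joint {path!r} coordinate range min must be < max")
        elif k == "marker":
            loc = np.asarray(comp.get("location"))
            w = comp.get("weight")
            if not np.all(np.isfinite(loc)) or not np.isfinite(w) or w < 0:
                raise ModelError(f"marker {path!r} needs finite location and weight >= 0")
        elif k == "contact":
            if comp.get("radius") <= 0:
                raise ModelError(f"contact {path!r} radius must be > 0")
            if comp.get("stiffness") < 0 or comp.get("dissipation") < 0:
                raise ModelError(f"contact {path!r} stiffness and dissipation must be >= 0")
            n = np.asarray(comp.get("plane_normal"))
            if abs(np.linalg.norm(n) - 1.0) > 1e-9:
                raise ModelError(f"contact {path!r} plane normal must be a unit vector")
        elif k == "coordinate_limit_force":
            if comp.get("stiffness") < 0 or comp.get("damping") < 0:
                raise ModelError(f"limit force {path!r} stiffness and damping must be >= 0")
            if not comp.get("lower") < comp.get("upper"):
                raise ModelError(f"limit force {path!r} requires lower < upper")
        elif k == "muscle":
            pts = comp.get("path")
            if pts is None or len(pts) < 2:
                raise ModelError(f"muscle {path!r} path needs at least 2 points")
            for bp, _loc in pts:
                tgt = paths.get(bp)
                if tgt is None or tgt.kind != "body":
                    raise ModelError(f"muscle {path!r} path references missing body {bp!r}")
        elif k == "controller":
            ct = comp.get("type")
            if ct == "prescribed":
                t = np.asarray(comp.get("times"))
                v = np.asarray(comp.get("values"))
                if t.ndim != 1 or t.shape != v.shape or (len(t) > 1 and not np.all(np.diff(t) > 0)):
                    raise ModelError(f"controller {path!r} breakpoint times must be strictly increasing")
                if np.any(v < 0) or np.any(v > 1):
                    raise ModelError(f"controller {path!r} excitation values must lie in [0, 1]")
            elif ct == "reflex":
                if comp.get("gain") < 0 or comp.get("delay") < 0:
                    raise ModelError(f"controller {path!r} gain and delay must be >= 0")
                if not 0.0 <= comp.get("baseline") <= 1.0:
                    raise ModelError(f"controller {path!r} baseline must lie in [0, 1]")
            else:
                raise ModelError(f"controller {path!r} has unknown type {ct!r}")


# ---------------------------------------------------------------------------
# structural equality (used by serialization round-trip checks)


def _prop_equal(a: Property, b: Property) -> bool:
    if a.units != b.units or type(a.value) is not type(b.value):
        return False
    va, vb = a.value, b.value
    if isinstance(va, np.ndarray):
        return va.shape == vb.shape and np.array_equal(va, vb)
    if isinstance(va, list):  # path points
        if len(va) != len(vb):
            return False
        return all(pa[0] == pb[0] and np.array_equal(pa[1], pb[1]) for pa, pb in zip(va, vb))
    return va == vb


def components_equal(a: ComponentSpec, b: ComponentSpec) -> bool:
    if (a.name, a.kind) != (b.name, b.kind):
        return False
    if a.sockets != b.sockets or a.inputs != b.inputs:
        return False
    if list(a.properties) != list(b.properties):
        return False
    if not all(_prop_equal(a.properties[k], b.properties[k]) for k in a.properties):
        return False
    if len(a.children) != len(b.children):
        return False
    return all(components_equal(ca, cb) for ca, cb in zip(a.children, b.children))


def models_equal(a: ModelSpec, b: ModelSpec) -> bool:
    """Structural equality of two model descriptions."""
    if a.name != b.name or not np.array_equal(a.gravity, b.gravity):
        return False
    if len(a.components) != len(b.components):
        return False
    return all(components_equal(x, y) for x, y in zip(a.components, b.components))
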
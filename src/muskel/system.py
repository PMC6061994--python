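"""Compiling a model description into an executable system plus state.

A validated model compiles to a :class:`SystemSpec`: the enumerated
generalized coordinates, the layout of the continuous state vector
(nq generalized coordinates q, nu generalized speeds u, nz auxiliary
variables z with one owner each), compiled multibody/muscle tables, and a
topologically sorted component evaluation order.  The system is treated as
immutable once built; everything that varies in time lives in the
:class:`State`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import muscle as _muscle
from .components import (
    DYNAMIC_INPUTS,
    GROUND_NAME,
    ModelError,
    ModelSpec,
    validate_model,
)
from .multibody import MultibodyTree, compile_multibody

__all__ = ["SystemSpec", "State", "CompiledMuscle", "build_system", "default_state"]

_PARAM_KEYS = (
    "F_max", "l_opt", "l_Ts", "alpha_opt", "v_max", "tau_act", "tau_deact",
    "gamma", "k_p", "e_0", "e_T0", "a_f", "f_ecc", "a_min",
)


@dataclass
class CompiledMuscle:
    name: str
    params: _muscle.MusculotendonParams
    path: list  # [(body name, location array), ...]
    rigid_tendon: bool
    a_slot: int  # index into z
    lm_slot: int = -1  # index into z (compliant only)


@dataclass
class State:
    """Time plus the continuous variables of a compiled system."""

    t: float
    q: np.ndarray
    u: np.ndarray
    z: np.ndarray

    def copy(self) -> "State":
        return State(self.t, self.q.copy(), self.u.copy(), self.z.copy())


@dataclass
class SystemSpec:
    model: ModelSpec
    gravity: np.ndarray
    mb: MultibodyTree
    muscles: list  # CompiledMuscle, declaration order
    nq: int
    nu: int
    nz: int
    z_owner: list  # (component name, slot label) per z entry
    eval_order: list  # component paths, topologically sorted
    cache_enabled: bool = True
    _kin_cache: dict = field(default_factory=dict, repr=False)

    @property
    def coordinates(self):
        return self.mb.coords

    def coordinate_index(self, name: str) -> int:
        for k, c in enumerate(self.mb.coords):
            if c.name == name:
                return k
        raise ModelError(f"unknown coordinate {name!r}")

    def muscle_index(self, name: str) -> int:
        for k, m in enumerate(self.muscles):
            if m.name == name:
                return k
        raise ModelError(f"unknown muscle {name!r}")


def _evaluation_order(model: ModelSpec) -> list:
    """Topological sort of component paths by input wiring.

    Edges through dynamics (delayed controller sensing) are ignored for the
    cycle check; reporters always evaluate last.  A cycle among the
    remaining, non-dynamic signal connections is an error.
    """
    paths = dict(model.walk())
    deps = {p: set() for p in paths}
    for p, comp in paths.items():
        for iname, src in comp.inputs.items():
            if (comp.kind, iname) in DYNAMIC_INPUTS:
                continue
            deps[p].add(src.rsplit(":", 1)[0])

    order = []
    done = set()
    visiting = set()

    def visit(p):
        if p in done:
            return
        if p in visiting:
            raise ModelError(f"dependency cycle among non-dynamic signals at {p!r}")
        visiting.add(p)
        for d in sorted(deps[p]):
            visit(d)
        visiting.discard(p)
        done.add(p)
        order.append(p)

    non_reporters = [p for p, c in paths.items() if c.kind != "reporter"]
    reporters = [p for p, c in paths.items() if c.kind == "reporter"]
    for p in non_reporters + reporters:
        visit(p)
    # reporters must come last regardless of declaration order
    return [p for p in order if paths[p].kind != "reporter"] + \
           [p for p in order if paths[p].kind == "reporter"]


def build_system(model: ModelSpec) -> SystemSpec:
    """Compile a model into a system of equations plus state layout.

    Deterministic and pure: rebuilding the same model yields an identical
    system (coordinate order is joint-tree preorder; z slots are all muscle
    activations in declaration order followed by compliant fiber lengths).
    """
    validate_model(model)
    mb = compile_multibody(model)

    muscles = []
    z_owner = []
    paths = dict(model.walk())
    muscle_comps = [(p, c) for p, c in paths.items() if c.kind == "muscle"]
    for p, comp in muscle_comps:
        overrides = {k: comp.get(k) for k in _PARAM_KEYS if comp.get(k) is not None}
        params = _muscle.MusculotendonParams(**overrides)
        path_pts = [(paths[bp].name, loc.copy()) for bp, loc in comp.get("path")]
        muscles.append(
            CompiledMuscle(
                name=comp.name, params=params, path=path_pts,
                rigid_tendon=bool(comp.get("rigid_tendon", True)),
                a_slot=len(muscles),
            )
        )
        z_owner.append((comp.name, "activation"))
    lm_base = len(muscles)
    n_compliant = 0
    for m in muscles:
        if not m.rigid_tendon:
            m.lm_slot = lm_base + n_compliant
            z_owner.append((m.name, "fiber_length"))
            n_compliant += 1

    nq = mb.nq
    return SystemSpec(
        model=model,
        gravity=np.asarray(model.gravity, dtype=float).copy(),
        mb=mb,
        muscles=muscles,
        nq=nq,
        nu=nq,
        nz=len(z_owner),
        z_owner=z_owner,
        eval_order=_evaluation_order(model),
    )


def default_state(system: SystemSpec) -> State:
    """State at t = 0: coordinates at their defaults, speeds zero,
    activations at the floor, compliant fiber lengths at optimal."""
    q = np.array([c.default for c in system.mb.coords], dtype=float)
    u = np.zeros(system.nu)
    z = np.zeros(system.nz)
    for m in system.muscles:
        z[m.a_slot] = m.params.a_min
        if m.lm_slot >= 0:
            z[m.lm_slot] = m.params.l_opt
    return State(t=0.0, q=q, u=u, z=z)
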
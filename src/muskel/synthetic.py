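"""Synthetic fixtures: every solver is testable without external data.

The generators produce small but fully valid models — pendulum chains for
dynamics checks, a planar two-link arm with antagonist muscle pairs for
muscle-driven simulation and tracking, and a drop-landing ankle model with
contact, ligament-like limit forces, and evertor/invertor muscles — plus
synthetic motion-capture marker tables and an isolated-muscle ramp-stretch
rig.  Dimensions and masses are loosely anthropometric but arbitrary,
documented constants with no claim of subject fidelity.  Everything is
bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import muscle as _mu
from .components import (
    ModelError,
    ModelSpec,
    make_body,
    make_contact,
    make_ground,
    make_joint,
    make_limit_force,
    make_marker,
    make_muscle,
    make_prescribed_controller,
    make_reflex_controller,
)
from .dataio import DataTable
from .multibody import point_kinematics
from .system import State, build_system

__all__ = [
    "make_pendulum",
    "make_planar_arm",
    "make_ankle_landing_model",
    "synth_markers",
    "ramp_protocol",
    "run_ramp_experiment",
    "run_landing",
]


def make_pendulum(n_links: int, masses=None, lengths=None, point_mass: bool = False) -> ModelSpec:
    """Serial pin chain in the x-y plane (pin axes +z), hanging along -y at
    q = 0, with a marker at each link end.

    Rod links carry the slender-rod inertia about their center; with
    ``point_mass`` the whole mass sits at the distal end with zero
    rotational inertia.
    """
    if n_links < 1:
        raise ModelError("a pendulum needs at least one link")
    masses = [1.0] * n_links if masses is None else list(masses)
    lengths = [1.0] * n_links if lengths is None else list(lengths)
    if any(m <= 0 for m in masses) or any(L <= 0 for L in lengths):
        raise ModelError("link masses and lengths must be positive")
    model = ModelSpec(name=f"pendulum{n_links}")
    model.add(make_ground())
    parent = "/ground"
    parent_offset = (0.0, 0.0, 0.0)
    for i in range(n_links):
        m, L = masses[i], lengths[i]
        if point_mass:
            com = (0.0, -L, 0.0)
            inertia = np.zeros((3, 3))
        else:
            com = (0.0, -L / 2.0, 0.0)
            I = m * L * L / 12.0
            inertia = np.diag([I, 0.0, I])
        body = f"link{i + 1}"
        model.add(make_body(body, m, com=com, inertia=inertia))
        model.add(
            make_joint(
                f"j{i + 1}", "pin", parent, f"/{body}",
                axis=(0, 0, 1), parent_offset=parent_offset,
            )
        )
        model.add(make_marker(f"tip{i + 1}", f"/{body}", (0.0, -L, 0.0)))
        parent = f"/{body}"
        parent_offset = (0.0, -L, 0.0)
    return model


# anthropometric-ish planar arm constants [m], [kg]
_ARM = dict(L1=0.30, L2=0.25, m1=2.0, m2=1.5)


def _muscle_lengths(model: ModelSpec, path, slack_ratio=0.6, opt_ratio=0.4):
    """Slack and optimal lengths from the path length in the default pose."""
    system = build_system(model)
    q = np.array([c.default for c in system.mb.coords])
    st = State(0.0, q, np.zeros_like(q), np.zeros(system.nz))
    named = [(p if p.startswith("/") else p, loc) for p, loc in path]
    pts = [(model.find(bp).name, np.asarray(loc, float)) for bp, loc in named]
    l0, _ = _mu.path_length_and_speed(pts, system, st)
    return slack_ratio * l0, opt_ratio * l0


def make_planar_arm(n_muscles: int = 2, compliant: bool = False) -> ModelSpec:
    """Two-link arm (shoulder and elbow pins, axes +z) with antagonist
    muscle pairs routed through via points, and two markers per link.

    ``n_muscles`` of 2 gives the elbow pair; 4 adds a shoulder pair; 6 adds
    a biarticular pair.  Muscle pairs are mirror-symmetric about the arm's
    long axis so the hanging pose is close to muscular equilibrium.
    """
    if n_muscles not in (2, 4, 6):
        raise ModelError("n_muscles must be 2, 4, or 6")
    L1, L2, m1, m2 = _ARM["L1"], _ARM["L2"], _ARM["m1"], _ARM["m2"]
    model = ModelSpec(name=f"planar_arm{n_muscles}")
    model.add(make_ground())
    model.add(make_body("upperarm", m1, com=(0, -L1 / 2, 0),
                        inertia=np.diag([m1 * L1**2 / 12, 0, m1 * L1**2 / 12])))
    model.add(make_body("forearm", m2, com=(0, -L2 / 2, 0),
                        inertia=np.diag([m2 * L2**2 / 12, 0, m2 * L2**2 / 12])))
    model.add(make_joint("shoulder", "pin", "/ground", "/upperarm", axis=(0, 0, 1),
                         coord_range=(-math.pi, math.pi)))
    model.add(make_joint("elbow", "pin", "/upperarm", "/forearm", axis=(0, 0, 1),
                         parent_offset=(0, -L1, 0), coord_range=(-2.8, 2.8)))
    model.add(make_marker("ua1", "/upperarm", (0.02, -0.10, 0)))
    model.add(make_marker("ua2", "/upperarm", (-0.02, -0.25, 0)))
    model.add(make_marker("fa1", "/forearm", (0.02, -0.08, 0)))
    model.add(make_marker("fa2", "/forearm", (0.0, -0.22, 0)))

    pairs = []
    # elbow pair, with a via point near the joint
    for sign, name in ((1.0, "elbow_flex"), (-1.0, "elbow_ext")):
        pairs.append((name, [
            ("/upperarm", (sign * 0.030, -0.18, 0)),
            ("/upperarm", (sign * 0.035, -0.29, 0)),
            ("/forearm", (sign * 0.030, -0.06, 0)),
        ], 500.0))
    if n_muscles >= 4:
        for sign, name in ((1.0, "shoulder_flex"), (-1.0, "shoulder_ext")):
            pairs.append((name, [
                ("/ground", (sign * 0.030, 0.05, 0)),
                ("/upperarm", (sign * 0.030, -0.12, 0)),
            ], 600.0))
    if n_muscles == 6:
        for sign, name in ((1.0, "biart_flex"), (-1.0, "biart_ext")):
            pairs.append((name, [
                ("/ground", (sign * 0.035, 0.06, 0)),
                ("/upperarm", (sign * 0.040, -0.28, 0)),
                ("/forearm", (sign * 0.028, -0.08, 0)),
            ], 400.0))
    for name, path, f_max in pairs:
        l_Ts, l_opt = _muscle_lengths(model, path)
        model.add(make_muscle(name, path, rigid_tendon=not compliant, params=dict(
            F_max=f_max, l_opt=l_opt, l_Ts=l_Ts, v_max=10.0,
        )))
    return model


def make_ankle_landing_model() -> ModelSpec:
    """Single-leg drop landing in miniature.

    A point-mass 'shank' rides a vertical slider; a foot segment hangs from
    an inversion pin at the ankle.  The lateral contact sphere sits lower
    than the medial one, so first ground contact drives the foot into
    inversion (positive coordinate) until the medial sphere engages;
    ligament mechanics are a coordinate-limit force and an evertor/invertor
    muscle pair crosses the ankle.  Preset co-activation and stretch-reflex
    controllers can be attached to the muscles.
    """
    model = ModelSpec(name="ankle_landing")
    model.add(make_ground())
    model.add(make_body("shank", 55.0, com=(0, 0, 0), inertia=np.diag([0.5, 0.5, 0.5])))
    model.add(make_body("foot", 1.0, com=(0.0, -0.04, 0), inertia=np.diag([0.008, 0.008, 0.008])))
    model.add(make_joint("drop", "slider", "/ground", "/shank", axis=(0, 1, 0),
                         default=0.32, coord_range=(-1.0, 2.0)))
    model.add(make_joint("ankle_inv", "pin", "/shank", "/foot", axis=(0, 0, 1),
                         parent_offset=(0, -0.08, 0), default=0.0, coord_range=(-1.2, 1.2)))
    model.add(make_contact("lateral", "/foot", center=(0.05, -0.062, 0), radius=0.02,
                           plane_point=(0, 0, 0), plane_normal=(0, 1, 0),
                           stiffness=6e4, dissipation=1.0))
    model.add(make_contact("medial", "/foot", center=(-0.05, -0.040, 0), radius=0.02,
                           plane_point=(0, 0, 0), plane_normal=(0, 1, 0),
                           stiffness=6e4, dissipation=1.0))
    model.add(make_limit_force("ankle_ligaments", "/ankle_inv", lower=-0.30, upper=0.30,
                               stiffness=40.0, damping=1.0))
    # mirror-symmetric evertor (-x side resists inversion) and invertor
    for sign, name in ((-1.0, "evertor"), (1.0, "invertor")):
        path = [("/shank", (sign * 0.05, -0.02, 0)), ("/foot", (sign * 0.05, -0.05, 0))]
        l_Ts, l_opt = _muscle_lengths(model, path, slack_ratio=0.47, opt_ratio=0.55)
        model.add(make_muscle(name, path, rigid_tendon=True, params=dict(
            F_max=800.0, l_opt=l_opt, l_Ts=l_Ts, v_max=10.0,
        )))
    model.add(make_marker("malleolus", "/foot", (0.0, 0.0, 0.0)))
    return model


def run_landing(coactivation: float = 0.0, reflex_gain: float = 0.0,
                reflex_delay: float = 0.04, t_end: float = 0.6,
                rtol: float = 1e-6, atol: float = 1e-8):
    """Simulate the drop landing and return ``(trajectory, peak inversion [rad])``.

    ``coactivation`` presets both muscles to a constant excitation;
    ``reflex_gain`` > 0 attaches a delayed stretch reflex to the evertor.
    """
    from .solvers import IntegratorSettings, build_controllers, integrate_forward
    from .system import default_state

    model = make_ankle_landing_model()
    if coactivation > 0.0:
        for mname in ("evertor", "invertor"):
            model.add(make_prescribed_controller(
                f"preset_{mname}", f"/{mname}", [0.0], [coactivation]))
    if reflex_gain > 0.0:
        model.add(make_reflex_controller("evertor_reflex", "/evertor",
                                         gain=reflex_gain, delay=reflex_delay,
                                         threshold=0.0, baseline=0.02))
    system = build_system(model)
    state0 = default_state(system)
    for m in system.muscles:
        state0.z[m.a_slot] = max(coactivation, m.params.a_min)
    ctrls = build_controllers(model, system)
    t_eval = np.linspace(0.0, t_end, 601)
    traj = integrate_forward(system, state0, t_end, controllers=ctrls,
                             settings=IntegratorSettings(rtol=rtol, atol=atol),
                             t_eval=t_eval)
    inv_idx = system.coordinate_index("ankle_inv")
    peak = float(np.max(traj.q[:, inv_idx]))
    return traj, peak


def synth_markers(model: ModelSpec, coord_table: DataTable, noise_sd: float = 0.0,
                  seed: int = 0) -> DataTable:
    """Marker trajectories for a coordinate table, emulating motion capture.

    Marker positions come from point kinematics; isotropic Gaussian noise of
    standard deviation ``noise_sd`` [m] is added per coordinate (seeded);
    ``noise_sd = 0`` gives exact positions.
    """
    system = build_system(model)
    coords = system.mb.coords
    missing = [c.name for c in coords if c.name not in coord_table.columns]
    if missing:
        raise ModelError(f"coordinate table is missing columns {missing}")
    rng = np.random.default_rng(seed)
    n = coord_table.nrows
    markers = system.mb.markers
    data = {m.name: np.zeros((n, 3)) for m in markers}
    for i in range(n):
        q = np.array([coord_table.columns[c.name][i] for c in coords])
        st = State(float(coord_table.time[i]), q, np.zeros_like(q), np.zeros(system.nz))
        for m in markers:
            x, _ = point_kinematics(system, st, m.body, m.location)
            data[m.name][i] = x
    if noise_sd > 0.0:
        for m in markers:
            data[m.name] += rng.normal(0.0, noise_sd, size=(n, 3))
    return DataTable(
        time=coord_table.time.copy(),
        columns=data,
        units={m.name: "m" for m in markers},
        meta={"Units": "m", "DataRate": float(round(1.0 / np.median(np.diff(coord_table.time))))
              if n > 1 else 0.0},
    )


# ---------------------------------------------------------------------------
# isolated-muscle ramp-stretch rig


@dataclass
class RampRun:
    amplitude: float  # [m]
    t_stretch_start: float
    t_stretch_end: float
    t_release_start: float
    t_release_end: float
    t_end: float

    def length(self, t: float, l0: float) -> float:
        if t < self.t_stretch_start:
            return l0
        if t < self.t_stretch_end:
            return l0 + self.amplitude * (t - self.t_stretch_start) / (self.t_stretch_end - self.t_stretch_start)
        if t < self.t_release_start:
            return l0 + self.amplitude
        if t < self.t_release_end:
            return l0 + self.amplitude * (1.0 - (t - self.t_release_start) / (self.t_release_end - self.t_release_start))
        return l0


def ramp_protocol(amplitudes=(1e-4, 2.5e-4, 5e-4, 1e-3), ramp_speed: float = 2e-3,
                  hold_time: float = 0.25) -> list:
    """Hold-stretch-hold-release length protocols, one per amplitude [m].

    Mirrors an isolated-muscle rig where the maximally excited muscle's free
    end is displaced by a predetermined signal at constant ramp speed, for a
    family of displacement amplitudes.
    """
    if any(a < 0 for a in amplitudes):
        raise ModelError("ramp amplitudes must be nonnegative")
    runs = []
    for A in amplitudes:
        ramp = A / ramp_speed if A > 0 else 0.0
        t1 = hold_time
        runs.append(RampRun(
            amplitude=A, t_stretch_start=t1, t_stretch_end=t1 + ramp,
            t_release_start=t1 + ramp + hold_time,
            t_release_end=t1 + 2 * ramp + hold_time,
            t_end=t1 + 2 * ramp + 2 * hold_time,
        ))
    return runs


def _rig_rest_length(params: _mu.MusculotendonParams, norm_fiber_length: float = 0.95) -> float:
    """Path length placing the fully active fiber at the given normalized
    length in isometric equilibrium (fiber starts on the ascending limb)."""
    l_M = norm_fiber_length * params.l_opt
    cos_a = math.cos(params.alpha_opt)
    f_T = (_mu.active_force_length(norm_fiber_length, params.gamma)
           + _mu.passive_force_length(norm_fiber_length, params.k_p, params.e_0)) * cos_a
    strain = brentq(lambda e: _mu.tendon_force_strain(e, params.e_T0) - f_T, 0.0, 0.5)
    return l_M * cos_a + params.l_Ts * (1.0 + strain)


def run_ramp_experiment(params: _mu.MusculotendonParams = None, protocol=None,
                        dt: float = 1e-3) -> list:
    """Run the ramp rig (prescribed path length, excitation 1.0 throughout)
    for each protocol entry; returns force tables with isometric reference.

    The muscle is simulated in prescribed-length mode: the skeleton is
    bypassed and the compliant-tendon fiber dynamics are integrated against
    the imposed musculotendon length.
    """
    params = params or MusculotendonParams_rat()
    protocol = protocol if protocol is not None else ramp_protocol()
    l0 = _rig_rest_length(params)
    lm0 = _mu.init_fiber_length(params, 1.0, l0)
    tables = []
    for run in protocol:
        def rhs(t, y):
            _, ldot, _ = _mu.fiber_equilibrium_and_derivative(
                params, 1.0, y[0], run.length(t, l0))
            return [ldot]

        t_eval = np.arange(0.0, run.t_end + dt / 2, dt)
        sol = solve_ivp(rhs, (0.0, run.t_end), [lm0], t_eval=t_eval,
                        rtol=1e-8, atol=1e-10, max_step=5e-3)
        force = np.zeros(len(sol.t))
        lmt = np.zeros(len(sol.t))
        for i, (t, lm) in enumerate(zip(sol.t, sol.y[0])):
            lmt[i] = run.length(t, l0)
            _, _, out = _mu.fiber_equilibrium_and_derivative(params, 1.0, lm, lmt[i])
            force[i] = out.force
        iso_idx = int(np.searchsorted(sol.t, run.t_stretch_start)) - 1
        tables.append(DataTable(
            time=sol.t, columns={"force": force, "path_length": lmt},
            units={"force": "N", "path_length": "m"},
            meta={"name": f"ramp_{run.amplitude:g}", "amplitude": run.amplitude,
                  "isometric_force": float(force[max(iso_idx, 0)]),
                  "stretch_window": (run.t_stretch_start, run.t_stretch_end),
                  "release_window": (run.t_release_start, run.t_release_end)},
        ))
    return tables


def MusculotendonParams_rat() -> _mu.MusculotendonParams:
    """Generic small-muscle parameters for the isolated ramp rig (documented
    stand-in; the rig demonstrates protocol shape, not a specific animal)."""
    return _mu.MusculotendonParams(
        F_max=3.0, l_opt=0.024, l_Ts=0.018, alpha_opt=0.0, v_max=10.0,
        e_T0=0.04,
    )
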
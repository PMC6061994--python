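# Methods

This note records the models implemented in `muskel`, their assumptions,
the defaults and why they were chosen, the numerical choices, and what the
synthetic fixtures do and do not demonstrate.

## Model / System / State separation

A model is a declarative component tree: bodies, joints, muscles, markers,
controllers, contact elements, coordinate-limit forces, and reporters,
wired by sockets (structural references) and input–output signal
connections. Compilation validates every invariant (unique sibling names,
resolvable sockets of the right kind, exactly one ground body, a body–
joint tree rooted at ground, typed property checks) and produces an
immutable system: coordinates enumerated in joint-tree preorder, a state
layout with `nq = nu` generalized coordinates and speeds plus `nz`
auxiliary variables (all muscle activations in declaration order, then
compliant fiber lengths), and a component evaluation order from a
topological sort of the signal graph. Signal connections whose effect
passes through dynamics — the delayed reflex sensing input — are excluded
from the cycle check; a cycle among the remaining instantaneous
connections is rejected. Reporters always evaluate last. Kinematic loops
and constraints are rejected at build time; this keeps `nq = nu` and
avoids constraint solvers entirely.

Kinematic results may be cached on the system keyed by the exact bytes of
`(q, u)`; the cache stores the result object of the identical computation,
so cached and uncached results are bitwise equal (a tested contract).

## Multibody dynamics

Bodies carry mass, center of mass, and a symmetric positive-semidefinite
rotational inertia (with the triangle inequality on principal moments
enforced). Joints are pin, slider, or weld, each defined by parent and
child frames and a unit axis. All quantities are SI (m, kg, s, rad, N);
frames are right-handed; gravity defaults to (0, −9.80665, 0) m/s².
Planar fixtures use the full 3-D spatial algebra with pin axes out of
plane — there is no planar special case.

The mass matrix is assembled by the composite-rigid-body algorithm and
the bias forces / inverse dynamics by a recursive Newton–Euler sweep in
6-D spatial (Plücker) coordinates, with gravity applied as a fictitious
base acceleration. Forward dynamics solves `M u̇ = τ + applied − bias` by
Cholesky factorization; a singular mass matrix (zero-mass chain) is an
explicit error. The engine is verified against an independently coded
textbook double-pendulum closed form (itself checked once against a
symbolic Lagrangian derivation) to 1e-10 absolute on the mass matrix and
1e-8 relative on inverse dynamics, and forward-then-inverse dynamics
closes the loop to 1e-8 N·m on random 1–4-link chains.

Contact is a single-point sphere–plane spring-damper,
`f = k δ (1 + c δ̇)` along the plane normal, clamped at zero so it is
never adhesive — a deliberately simple stand-in for distributed-pressure
(elastic-foundation) contact; friction is omitted. It is sufficient for
the drop-landing fixture and nothing more is claimed for it. The
coordinate-limit force is zero inside `[lower, upper]` and
`−K (q − limit) − D u` beyond, with damping applied only while beyond the
limit so the element is passive; the force is continuous in `q` at the
limit (the damping term switches on discontinuously with penetration,
which is acceptable for a ligament-like element).

## Musculotendon model

Curve parameterizations (all dimensionless, force normalized by `F_max`):

| curve | form | anchors |
| --- | --- | --- |
| active force–length | Gaussian `exp(−(l̃−1)²/γ)` | `f_L(1) = 1`; width `γ = 0.45` |
| passive force–length | `(e^{k_p(l̃−1)/e_0} − 1)/(e^{k_p} − 1)`, 0 below `l̃ = 1` | `f_PE(1+e_0) = 1`; `k_p = 4`, `e_0 = 0.6` |
| force–velocity, concentric | Hill hyperbola `(1+ṽ)/(1−ṽ/a_f)` | `f_V(−1) = 0`, `f_V(0) = 1`; `a_f = 0.25` |
| force–velocity, eccentric | saturating `f_ecc − (f_ecc−1)/(1+kṽ)` | C¹ at `ṽ = 0`; plateau `f_ecc = 1.4` |
| tendon force–strain | exponential toe, then linear with matched slope | `f_T(e_T0) = 1`; `e_T0 = 0.04`, toe shape `k_toe = 3` |

Defaults follow common Hill-model practice; every shape constant is a
field of `MusculotendonParams` and configurable per muscle. The passive
curve's exponent is capped (at 60) purely so out-of-range trial lengths
probed by root finders and ODE steppers stay finite.

Pennation uses the constant-width model `l_M sin α = l_opt sin α_opt`,
with `cos α` floored at 0.1 (α capped at 84.26°) to avoid the singularity;
rigid-tendon geometry that would require a larger angle is an error.

Activation dynamics are first order with `τ_act = 15 ms` on rising
excitation and `τ_deact = 50 ms` on falling, with a floor
`a_min = 0.01` that guards the force–velocity inversion in
compliant-tendon mode (configurable).

**Rigid tendon.** The tendon is inextensible at slack length; fiber length
and velocity follow algebraically from the path (`l̇_M = v_MT cos α`) and
the force on the skeleton is `F_max (a f_L f_V + f_PE) cos α`, clamped at
zero.

**Compliant tendon.** The state variable is the (un-normalized) fiber
length. At each instant the tendon force is computed from
`l_T = l_MT − l_M cos α`, the equilibrium
`f_T = (a f_L f_V + f_PE) cos α` is solved for the force–velocity
multiplier, and the force–velocity curve is inverted in closed form for
the fiber velocity. Targets outside `(0, f_ecc)` clamp the velocity (at
−1 for zero target, per the hyperbola) and flag the output; unclamped
solves leave an equilibrium residual at machine precision (the tested
bound is 1e-9). The isometric initializer solves the `ṽ = 0` equilibrium
by bracketed Brent root finding on
`l_M ∈ [0.05 l_opt, 2.2 l_opt]`; an empty bracket is an error.
`fiber_equilibrium_and_derivative` accepts the path lengthening speed for
interface symmetry with the rigid-tendon mode, but the equilibrium
formulation determines fiber velocity from the force balance alone.
Shrinking `e_T0` to 1e-4 reproduces rigid-tendon forces within 0.01 % on
a ramp stretch (excluding the short transients after the ramp's velocity
discontinuities, where the rigid model jumps instantaneously and the
compliant model relaxes over a sub-millisecond tendon time constant).

**Path geometry.** Paths are straight segments through via points; length
is the segment sum and speed the exact inner-product derivative from
point velocities. Moment arms use the tendon-excursion method
(`r = −∂l_MT/∂q`) with Richardson-refined central differences at base
step 1e-6 — uniform across path types rather than analytic per-geometry
derivatives — and are verified against the independent virtual-work route
(unit tension through point Jacobians) to 1e-6 relative.

**Energetics.** Muscle power is an Umberger-style partition:
`Ė = m_M (A a + M a f_L) + S a max(−ṽ, 0) F_max v_max l_opt +
max(−F_fiber l̇_M, 0)` plus a whole-body basal rate, with documented
defaults A = 40 W/kg, M = 74 W/kg, S = 0.25, B = 1.2 W/kg; the total
never falls below basal. The length dependence of the maintenance term
uses `f_L`. When a muscle mass is not given, reporters derive one from
PCSA = `F_max / σ` with σ = 0.25 MPa and density 1059.7 kg/m³. These
coefficients are a deliberate simplification for desk-scale energetics,
not a calibrated physiological model.

## Controllers

Prescribed controllers interpolate `[0, 1]`-bounded breakpoints piecewise
linearly with constant extrapolation. The stretch reflex is a
single-gain velocity reflex,
`u = clamp(u₀ + G max(ṽ(t−d) − ṽ_thr, 0), u₀, 1)`, sensing the
normalized fiber lengthening velocity; combined length-plus-velocity
gains exist in the literature but the single-gain form is the simplest
that exhibits delayed stretch response, and is what the causality
experiments need. The delay is implemented by buffered linear
interpolation rather than a delay-differential solver: forward
integration proceeds in chunks of `d/4` (also the integrator's maximum
step when a reflex is present) and the sensed signal is committed to the
buffer only at accepted chunk boundaries, so the excitation at time `t`
depends exclusively on committed samples at times ≤ `t − d + d/4` and —
exactly, when the sensing time falls on a committed boundary — on the
state at `t − d`. Within-chunk reads never touch uncommitted (rejected or
in-progress) integrator states. A read before the oldest sample is an
underrun: the controller returns its baseline and flags the buffer.

## Solvers

**Forward integration** assembles `(q̇ = u; u̇ = forward dynamics under
muscle, contact, limit, and user-applied forces; ż = activation and fiber
derivatives)` and integrates with SciPy's adaptive Runge–Kutta (RK45 by
default, rtol 1e-8 / atol 1e-10); auxiliary variables are clamped to
their bounds in the derivative and on output. Tightening tolerances
tenfold changes the final state by well under 1e-4 relative (tested).

**Inverse kinematics** solves each frame's weighted least squares with a
damped (Levenberg) Gauss–Newton iteration using analytic marker
Jacobians; damping guarantees a non-increasing objective. Frames are
solved in time order with warm starting; weights default to the marker
components' weights; a rank-deficient Jacobian is an error naming the
frame. Table markers that match no model marker are dropped with a
warning; frames flagged invalid by the TRC reader are skipped and
reported rather than interpolated. Tables in millimeters must be
converted explicitly first. No temporal smoothing is applied — the
formulation is strictly per frame.

**Inverse dynamics over trajectories** differentiates the coordinate
columns with a 3-point central scheme (second-order one-sided at the
ends), optionally after a zero-phase second-order Butterworth low-pass
whose cutoff is an explicit, logged setting. Sampling must be uniform:
timestamps are compared to the ideal uniform grid with a 0.5 %-of-dt
tolerance so file-precision rounding passes but genuinely non-uniform
tables are rejected (or accepted explicitly with a flag). Only explicitly
supplied external forces are credited; model passive elements are not
silently included.

**Static optimization** distributes target torques among rigid-tendon
muscles by minimizing `Σ a_iᵖ + W Σ ρ_j²` with reserve actuators ρ and
`a ∈ [a_min, 1]`. With `p = 2` (default) the rigid-tendon force is affine
in activation, so after eliminating the reserves the problem is a
bound-constrained linear least squares solved exactly (BVLS); the
reserve penalty defaults to `W = 1e3`. Other exponents fall back to a
bound-constrained quasi-Newton solve (L-BFGS-B) with the analytic
gradient. Verified against the analytic KKT point for one muscle (1e-6)
and a 1e-3-resolution brute-force grid for two (2e-3).

**CMC-lite** is a deliberately simplified computed-muscle-control loop:
desired accelerations `u̇* = q̈̂ + k_v (q̇̂ − u) + k_p (q̂ − q)` with the
reference evaluated at the end of the lookahead window `t + T` (the
lookahead-target formulation; on the arm fixture this roughly halves the
tracking error relative to evaluating at `t`), inverse dynamics for the
target torques (crediting model contact/limit forces), static
optimization for desired activations, and closed-form inversion of the
activation dynamics for constant excitations over the window. Reserve
torques from static optimization are applied during the window by
default. There is no moving-horizon optimization and no error-weighting
matrix. Defaults `k_p = 100 s⁻²`, `k_v = 20 s⁻¹`, `T = 10 ms` are
documented, configurable, and carry no claim of matching any production
controller's numbers; with them the closed loop tracks a muscle-driven
arm reference with ≈1.6° RMSE over 1 s (the tested bound is 2°).

## Data formats

TRC (tab-separated marker trajectories with typed header rows) and
STO/MOT (`key=value` header, `endheader`, labels, rows) are implemented
as documented dialects; MOT is treated as STO with the same `inDegrees`
handling. Units are metadata: a millimeter TRC stays in millimeters until
`trc_to_meters` is called, and a degrees table converts only via
`degrees_to_radians` — never silently. Writers are deterministic (6
significant digits for TRC, 8 for STO, configurable), and the TRC rate
field is computed from the median timestep when not supplied. Write→read
round trips are lossless at the declared precision (tested on 50 seeded
random tables per format). C3D (binary) and CSV dialect guessing are
out of scope; a conversion hook (any table → `DataTable`) is the
extension point.

## Synthetic fixtures — what they show and what they do not

All fixture dimensions and masses are loosely anthropometric but
arbitrary, documented constants; no subject fidelity is claimed.
Everything is bit-reproducible given the seed.

* **Pendulum chains** (1–4 links, rod or point-mass): conventions match
  the closed-form oracle (angles from straight down, pin axes +z).
  They exercise the dynamics engine, energy conservation, and the
  ID-over-trajectory round trip.
* **Planar arm** (2 links; 2, 4, or 6 muscles in mirror-symmetric
  antagonist pairs with via points; rigid or compliant tendons): the
  hanging pose is near muscular equilibrium by symmetry. It exercises the
  marker pipeline (4 markers, 2 coordinates), moment arms, static
  optimization, and CMC tracking.
* **Ankle landing**: a 55 kg "shank" on a vertical slider drops ~0.14 m
  onto the floor; the foot's lateral contact sphere sits 10 mm lower than
  the medial one, so first contact drives inversion until the medial
  sphere engages; a coordinate-limit force plays the ligament and an
  evertor/invertor pair crosses the ankle. Preparatory co-activation at
  0.6 lowers peak inversion by ≈2.3° versus the passive drop — the
  qualitative co-activation effect, at miniature scale. A stretch reflex
  whose delay exceeds the time to peak inversion contributes nothing
  before the peak (causality), which is the point of the demonstration.
* **Ramp-stretch rig**: an isolated, maximally excited compliant-tendon
  muscle in prescribed-length mode (the skeleton is bypassed entirely) is
  held, stretched at 2 mm/s by 0.10–1.00 mm, held, and released, starting
  from isometric equilibrium on the ascending limb (`l̃ = 0.95`). Forces
  rise above the isometric level during stretch, fall below it during
  release, and peak forces are nondecreasing in amplitude. These are
  protocol-shape properties only; no published force values are
  reproduced, and the generic parameters are not a specific animal's.
* **Synthetic markers**: exact marker positions from the kinematics plus
  seeded isotropic Gaussian noise. Zero noise closes the IK loop to
  1e-6 rad; 1 mm noise yields coordinate errors of a few milliradians.

Passing tests on these fixtures demonstrate internal consistency and
agreement with closed forms at desk scale. They do not demonstrate
fidelity to real musculoskeletal data: there is no muscle wrapping, no
friction, no kinematic loops or ball joints, no fatigue or
history-dependent muscle force, and the fixtures' parameters are not fit
to measurements.

## Problem sizes

The default test suite and the acceptance script run simulations of a few
seconds on models with ≤ 4 coordinates and ≤ 6 muscles (5 s passive
swings, 200-frame IK, 1 s CMC tracking, 0.5 s drop landings, four ramp
runs) — sizes chosen so the whole verification cycle completes in well
under a minute on one CPU while still exercising every code path.
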
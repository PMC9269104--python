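# Methods

This note documents the models, numerical methods and design choices in
`skitrack`, in the spirit of a model-description appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic tests do and do not demonstrate.

## Multibody model

The skier is a tree of rigid segments (pelvis root, trunk with head and
arms folded in, thigh–shank–foot per leg) with 19 generalized coordinates:
a 6-DOF free joint between pelvis and ground, a 3-DOF lumbar joint, and
3 + 1 + 1 DOF at each hip, knee and ankle. Ball and free joints are
parameterized by an ordered triple of fixed rotation axes composed by
Rodrigues formulas. The axes are chosen anatomically so that positive
coordinates match the reporting conventions (hip flexion, adduction and
internal rotation, knee extension, ankle dorsiflexion, lumbar extension,
lateral bend and left rotation positive); the knee coordinate is therefore
negative in flexion. Gimbal singularities of the three-axis sequences lie
far outside skiing postures.

Equations of motion are evaluated in implicit form. A world-frame
recursive pass computes every body's pose, twist and acceleration; the
generalized force required by a motion, `τ_id(q, q̇, q̈)`, follows by
projecting each body's Newton–Euler balance onto the coordinate axes. The
residual `τ_id − τ_applied`, stacked with the kinematic identity
`q̇ − v`, the implicit Hill contraction residual and the activation
residual, constitutes the system function `f(x, ẋ, u)` used everywhere
(simulation and transcription alike). All evaluation code is batched over
time samples and preserves complex dtype, because all derivatives are
taken by complex-step perturbation (exact to machine precision; verified
against central finite differences in the tests).

Anthropometry defaults to a 75 kg, 1.78 m subject with literature-style
segment mass fractions and box/rod inertias, scaled by configured body
mass and height. These are stand-ins: segment-exact inertias of any
particular subject should be supplied via the configuration.

Each ski is 18 segments (7 rear, 1 center, 10 front) of equal length,
summing exactly to 2.02 m and 2.1 kg, joined by transverse revolute
joints; torsion is omitted. Rotational spring-dampers at the bending
joints use a quadratic stiffness profile (2000 N·m/rad at the binding
falling to 300 N·m/rad at tip and tail, damping 3 % of stiffness per
second); the profile is plausible for a giant-slalom ski but not
bench-validated, and fully configurable. Edge half-width at each segment
follows the 32 m sidecut arc from a 65 mm waist.

## Muscles

Hill-type musculotendon actuators with the projected fiber length `s`
(contractile element length along the tendon) as the muscle state.
Constant-height pennation: fiber length `l_f = sqrt(s² + (l_opt sin α₀)²)`.
Normalized curves: Gaussian active force–length (width 0.45, exactly 1 at
optimum), logistic force–velocity (exactly 1 at zero velocity, floor 0.2
in fast shortening, 1.8 eccentric ceiling), exponential parallel element
(0 at optimum, 1 at 60 % stretch), and a linear-elastic tendon above slack
(35 Fmax per unit strain) with a C1 softplus toe (strain scale 2·10⁻³).
The contraction residual enforces the tendon/fiber force balance
implicitly; no force–velocity inversion is ever needed.

Activation dynamics is the standard first-order lag with τ_act = 10 ms and
τ_deact = 40 ms; the time-constant switch at e = a is blended by a
logistic in `e − a` (default sharpness 50) so the residual is smooth for
the optimizer. At |e − a| = 1 the blend error is below 10⁻²¹, so the
branch values are exact in practice.

Muscle routing is polynomial: `l_mt(q)` is a polynomial over the spanned
coordinates, so moment arms `R = −∂l_mt/∂q` are exact. The reduced default
set has 12 muscles (per leg: hip flexors, glutei, vasti, biarticular
hamstrings; plus paired lumbar extensors and abdominals) with constant
moment arms, calibrated so fibers sit at optimum in a crouched reference
posture. The full 94-muscle layout (43 per leg, 8 lumbar) reproduces the
size and bookkeeping of the complete model with generic parameters; the
cadaver-derived parameter sets of the source models are not reproduced.

The ski boot is a passive ankle moment: zero at 15° dorsiflexion, cubic
stiffening (15 N·m/rad linear + 4000 N·m/rad³) plus 1.5 N·m·s/rad damping;
dorsiflexion beyond neutral yields negative (plantarflexion-direction)
moments.

## Ski–snow contact

Contact acts at both lateral edges of each ski segment's midpoint. When
the ski rolls, only the lower edge penetrates, so edge selection is
implicit and smooth in the roll angle. Per edge, with depth `d`, depth
rate `ḋ`, edging angle `θ` and segment length `L`:

* penetration force `F_p = k_p L ⌈d⌉ g(θ) ⌈1 + c_p ḋ⌉` along the snow
  normal, with `⌈·⌉` a smooth positive ramp (no adhesion, ever) and
  `g(θ) = 1/√(sin²θ + 1/g_cap²)`: a flat ski spreads load over the base
  (stiff response), an edged ski concentrates it and penetrates deeper;
* shear `F_s = −k_s L ⌈d⌉ sat(v_lat) l̂` in the snow plane, orthogonal to
  the edge, opposing lateral slip with a smooth saturation
  `sat(x) = x/√(x² + v_eps²)`;
* friction `F_f = −μ F_p v/√(‖v‖² + v_eps²)` with μ = 0.1.

Defaults: `k_p = 3·10⁴ N/m²`, `k_s = 4·10⁵ N/m²`, `c_p = 0.2 s/m`,
`g_cap = 2`, `v_eps = 0.05 m/s`, depth smoothing 1 mm. They describe a
firm but penetrable groomed slope: a 75 kg skier standing flat sinks a few
millimeters, an edged ski bites one to a few centimeters. Two of these
values deserve comment. The slip regularization speed is deliberately a
few cm/s: a much smaller value makes the lateral-slip boundary layer far
stiffer than anything a 20–50 Hz collocation grid can resolve and
dominates the constraint curvature the optimizer must fight. The smoothing
floor means exactly-airborne segments feel residual forces of a few
newtons; this is the price of C1 contact and is negligible against
operating loads (~10²–10³ N). None of these constants are calibrated
against bench data; all are configuration parameters.

A carving testbed (a point load on a mast over one ski, roll and pitch
held by stiff spring-dampers, a light yaw damper against the rig's weaving
mode) exercises the self-steering behavior: with the defaults a loaded
default ski at 14 m/s carves tighter than its 32 m sidecut radius once
edged, and the radius drops steeply from ~32 m at 10° edging to under
20 m at 25°. At extreme edging (45°) the very deep penetration makes the
steady radius settle slowly and slightly above the 25° value; see
Limitations.

## Tracking optimal control

Objective (per unit time): tracking error of the measured channels
(`w1 = 1` per channel; angles rad⁻², translations m⁻²), summed squared
activations as the effort surrogate (`w2 = 0.1`), and `w3 = 10⁻⁴` times
the squared state and control derivatives as regularization. The weights
of the original analyses are not published; these defaults were chosen
once for balanced magnitudes and are exposed in the configuration. An
optional GRF-magnitude tracking term (default weight 0) is available when
measured forces exist.

Transcription: implicit Euler collocation on N nodes (default one node per
measurement sample), decision vector `[x_k, u_k]` per node, equality
constraints `f(x_k, (x_k − x_{k−1})/h, u_k) = 0`, left-rectangle quadrature
of the objective. Residual rows are scaled to comparable magnitude
(dynamics rows by 1/(0.3·m·g), activation rows by 1/25). The objective is
exactly quadratic in the decision vector; the constraint Jacobian is
block-bidiagonal and assembled from 2·(n_x + n_u) parity-colored
complex-step sweeps, each one batched residual evaluation.

The solver is a sparse Gauss–Newton SQP: at each iteration the KKT system
(objective Hessian + adaptive proximal damping, exact constraint
Jacobian) is factorized once (sparse LU) and reused for a second-order
correction step; globalization is a backtracking line search on an ℓ1
merit function with a Levenberg-style damping update, and iterates are
projected onto the box bounds. Convergence is declared at scaled
feasibility ≤ 10⁻⁴ (≈0.02 N·m on dynamics rows, ≈0.5 N on muscle force
balances) and projected-gradient stationarity ≤ 10⁻³.

Because the skier's contact dynamics are both stiff and unstable over a
horizon, cold starts benefit from the two-phase driver `solve_tracking`:
phase one minimizes the tracking objective plus a proximal anchor to the
initial guess (projecting the guess onto the dynamics manifold without
leaving the maneuver), phase two drops the anchor; each phase restarts the
SQP while restarts keep improving feasibility, since a stale damping state
can stall an otherwise convergent iteration. Tracking problems also anchor
the initial pose and rates softly (quadratic penalty, not hard bounds —
hard equality pins interact badly with the projected line search). Without
that anchor the optimizer can discover degenerate optima, e.g. launching
the skier ballistically so the angle channels are tracked in flight.

An unmodified scipy `trust-constr` backend is available for small
problems and serves as an independent cross-check on the toys.

## Synthetic data

No measured skier data ships with the package. The generator builds a
kinematic turn template: the pelvis follows an arc of the target radius at
the requested entry speed on the inclined plane, in a crouched posture
with a gentle flexion–extension cycle, leaning into the turn by the
centripetal-equilibrium angle. Two numerical consistency passes make the
template physically sensible: the pelvis rotation and tilt are solved per
node so that the *skis* (not the pelvis) align with the heading and lie
parallel to the snow — with large lean and flexion the chained rotations
couple strongly into ski yaw and pitch — and the pelvis height is solved
per node so the static penetration-force balance carries the skier's
weight. Tracking this template with the standard solver yields the
dynamically consistent "truth"; i.i.d. Gaussian noise (default SD 1°,
seeded) on the angle channels then produces the synthetic measurement
data. Pelvis translations are left noise-free by default; the generator
emulates the channel structure and rate (50 Hz) of field kinematics, not
any particular camera error model.

Default conditions of the shipped turn emulate the measured maneuver's
regime (entry near racing speed on a moderate slope, target radius well
inside the sidecut radius). The end-to-end tests and the acceptance script
run a scaled-down instance — 8 m/s entry speed, a 28 m target radius, a 1.2 s horizon at 25 Hz on the reduced model (11 skier DOFs, 3-segment skis, 12 muscles) — so the whole recovery pipeline fits in minutes; the problem sizes are stated in
the test code.

The kinematic template is a target, not a feasible motion: the reduced
model (no hip ab/adduction) cannot ride it exactly, so the consistent
truth deviates from the template by several degrees while preserving the
turn. What passing these tests shows: the full pipeline — template,
consistent truth, noise, tracking recovery — closes with dynamically
consistent estimates, physiological joint moments (peak lumbar, hip and
knee moments near 1.3-1.7 N*m/kg on the shipped turn), moment waveforms
recovered from noisy kinematics alone (aggregate correlation ~0.9, peak
errors within ~15%), and ground reaction forces near one body weight.
What it does not show: exact joint-angle recovery. With the default
weights the objective is effort-dominated (the tracking term at the
1-degree noise floor is two orders of magnitude smaller than the muscle
effort term), so the knee and lumbar angles are identifiable only to a
few degrees: distinct local optima with near-identical objective values
differ by ~5-7 degrees in knee flexion, and the recovery legitimately
lands in one of them. Nor does it show fidelity to any real skier's joint
moments, which depends on subject-specific anthropometry, muscle
parameters, and snow properties that the defaults only stand in for.

## Numerical choices and degenerate inputs

* Implicit Euler everywhere (simulation and collocation): first-order,
  dissipative, and consistent between fixture generation and tracking.
  The forward simulator halves its step recursively when a Newton stage
  fails (stiff contact transients).
* Complex-step derivatives require every model function to be holomorphic;
  all switching laws (ramps, saturations, time-constant switches) are
  smooth by construction, which the optimizer needs anyway.
* The turn-radius estimator is an algebraic circle fit over a sliding
  window (default 0.5 s); windows that are numerically colinear are capped
  at 1000 m and flagged straight. Speeds are central differences of the
  hip-midpoint after a short odd-reflection moving average.
* Muscle-fiber initial guesses solve the isometric force balance by
  bisection; the tracking initial guess differentiates positions with
  backward differences, consistent with the collocation formula.
* Degenerate inputs raise typed errors naming the offending field (model
  validation, motion-file parsing with line numbers, config key checks).

## Limitations

* The reduced test model locks hip ab/adduction, so a leaned skier rides
  mostly on the inside ski's edges; load sharing between skis in the
  reduced fixtures is not representative of the full model.
* The carving testbed's steady radius is not strictly monotone up to 45°
  edging with the default soft snow (very deep penetration at extreme
  edging settles slowly); monotone steepening is robust over 10°–25°.
* The activation/deactivation switch blending and contact smoothing trade
  physical sharpness for optimizer-friendly curvature; both sharpness
  scales are configurable.
* The 94-muscle layout is structural: counts, names and bookkeeping match
  the full model, but its force and routing parameters are generic.
* Ski torsion, boot shell compliance, arm articulation, pole contact,
  snow memory (ruts, plowing) and aerodynamics are out of scope.
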
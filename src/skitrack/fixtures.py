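"""Synthetic inputs: oracle micro-models and reference turning/schussing data.

No measured skier data ships with the package.  All end-to-end tests run on
synthetic kinematics that emulate the structure of a field measurement
campaign — skier degrees of freedom sampled at 50 Hz with additive Gaussian
angular noise — generated by solving a small tracking problem toward a
kinematic turn template, so the reference ("truth") trajectories are
dynamically consistent by construction.

The reduced test model (11-DOF skier: 6 pelvis + lumbar flexion + hip
flexion and knee per leg; 3-segment skis; 12 muscles) keeps these
optimizations small enough for routine testing; the full 53-DOF, 94-muscle
layout is exercised by structural checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model_core as mc
from .model_core import MultibodyModel, Segment, Joint, SkiSpec
from .muscles import MuscleSet, default_muscle_set
from .ski_snow import ContactParams, SnowPlane
from .system import SkiSystem
from .tracking import (
    ObjectiveWeights,
    Solution,
    TrackingData,
    TrackingProblem,
    initial_guess,
    solve_tracking,
)

__all__ = [
    "SyntheticTurnSpec",
    "FixtureError",
    "make_oracle_models",
    "reduced_system",
    "full_system",
    "carving_ski_system",
    "synthesize_turn",
    "make_schuss_reference",
]


class FixtureError(RuntimeError):
    """A synthetic-data generator could not produce a valid fixture."""


# --------------------------------------------------------------------------
# oracle micro-models
# --------------------------------------------------------------------------

def make_oracle_models() -> dict:
    """Minimal models with closed-form reference dynamics.

    * ``pendulum``: point mass m=1 kg on a massless rod L=1 m, revolute about
      y; q measured from straight down, eom qdd = -(g/L) sin q.
    * ``double_pendulum``: two such links (reference by high-accuracy
      energy-conserving integration).
    * ``point_mass_on_plane``: 1 kg point mass with a degenerate single-edge
      'ski' so the snow contact model applies; on a frictionless plane the
      in-plane acceleration is exactly g*sin(alpha).
    """
    g = mc.GRAVITY
    out = {}

    def link(name, parent, L=1.0, m=1.0):
        return (
            Segment(name, m, np.zeros((3, 3)), np.array([0.0, 0.0, -L]), L),
            Joint(f"{name}_pivot", "revolute", parent,
                  np.zeros(3) if parent < 0 else np.array([0.0, 0.0, -L]),
                  np.array([[0.0, 1.0, 0.0]]), [f"{name}_angle"]),
        )

    pend = MultibodyModel("pendulum")
    pend.add_body(*link("link1", -1))
    out["pendulum"] = pend.finalize()

    dpend = MultibodyModel("double_pendulum")
    dpend.add_body(*link("link1", -1))
    dpend.add_body(*link("link2", 0))
    out["double_pendulum"] = dpend.finalize()

    pm = MultibodyModel("point_mass_on_plane")
    seg = Segment(
        "mass", 1.0, 1e-6 * np.eye(3), np.zeros(3), 0.0,
        meta={"ski_segment": True, "seg_length": 1.0, "half_width": 0.0},
    )
    pm.add_body(
        seg,
        Joint("root", "free", -1, np.zeros(3),
              np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]),
              ["tx", "ty", "tz", "rx", "ry", "rz"]),
    )
    out["point_mass_on_plane"] = pm.finalize()
    out["gravity"] = g
    return out


# --------------------------------------------------------------------------
# reduced and full systems
# --------------------------------------------------------------------------

#: coordinates locked in the reduced test model
_REDUCED_LOCKS = [
    "lumbar_bending", "lumbar_rotation",
    "hip_adduction_r", "hip_rotation_r", "hip_adduction_l", "hip_rotation_l",
    "ankle_dorsiflexion_r", "ankle_dorsiflexion_l",
]

#: reference crouched posture used for templates and initial guesses
_CROUCH = {
    "hip_flexion_r": 0.9, "hip_flexion_l": 0.9,
    "knee_flexion_r": -1.0, "knee_flexion_l": -1.0,
    "lumbar_extension": -0.35,
}


def reduced_system(slope_deg: float = 15.0, ski_segments=(1, 1, 1),
                   contact: ContactParams | None = None) -> SkiSystem:
    """Reduced skier (11 DOF) + 3-segment skis + 12 muscles on a slope."""
    skier = mc.build_skier_model({"locked": _REDUCED_LOCKS})
    spec = SkiSpec(n_rear=ski_segments[0], n_center=ski_segments[1],
                   n_front=ski_segments[2])
    model = mc.assemble_full_model(skier, mc.build_ski_model(spec), mc.build_ski_model(spec))
    muscles = default_muscle_set(model, _CROUCH)
    snow = SnowPlane.inclined(np.deg2rad(slope_deg))
    return SkiSystem(model, muscles, snow, contact or ContactParams())


def full_system(slope_deg: float = 15.0) -> SkiSystem:
    """Full 53-DOF model with the 94-muscle layout (structural contract)."""
    from .muscles import full_muscle_layout

    skier = mc.build_skier_model()
    model = mc.assemble_full_model(skier, mc.build_ski_model(), mc.build_ski_model())
    muscles = full_muscle_layout(model)
    return SkiSystem(model, muscles, SnowPlane.inclined(np.deg2rad(slope_deg)))


def carving_ski_system(edging_deg: float, load_mass: float = 40.0,
                       slope_deg: float = 15.0, ski: SkiSpec | None = None,
                       hold_stiffness: float = 2e4) -> SkiSystem:
    """A single loaded ski held at a fixed edging angle (carving testbed).

    A point load rides 0.5 m above the ski on a mast attached to the world
    by a free joint; stiff rotational spring-dampers hold the mast's roll at
    the requested edging angle and its pitch level, while yaw and all
    translations stay free.  Forward-simulating this system isolates the
    self-steering (carving) behavior of the contact model.
    """
    model = MultibodyModel("carving_ski")
    mast = Segment("mast", load_mass, 0.5 * np.eye(3), np.array([0.0, 0.0, 0.5]))
    model.add_body(
        mast,
        Joint("root", "free", -1, np.zeros(3),
              np.array([[0.0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]]),
              ["tx", "ty", "tz", "yaw", "roll", "pitch"]),
    )
    mc.graft_model(model, mc.build_ski_model(ski or SkiSpec()), 0, np.zeros(3))
    model.finalize()
    sysm = SkiSystem(model, MuscleSet([]), SnowPlane.inclined(np.deg2rad(slope_deg)))
    th = np.deg2rad(edging_deg)
    c_hold = 2.0 * np.sqrt(hold_stiffness * load_mass * 0.25)
    sysm.extra_springs = [
        ("roll", hold_stiffness, c_hold, th),
        ("pitch", hold_stiffness, c_hold, 0.0),
        # pure yaw damper: suppresses the rig's weaving mode without
        # constraining the steady-state yaw rate appreciably
        ("yaw", 0.0, 10.0, 0.0),
    ]
    return sysm


# --------------------------------------------------------------------------
# synthetic turn
# --------------------------------------------------------------------------

@dataclass
class SyntheticTurnSpec:
    """Conditions of a synthetic turning maneuver.

    Defaults emulate the measured maneuver's regime: ~14 m/s on a moderate
    slope with a target radius well inside the 32 m sidecut radius, skier
    kinematics sampled at 50 Hz, 1 degree additive angular noise.
    """

    speed: float = 14.0            # m/s initial speed along the fall line
    slope_deg: float = 15.0        # slope inclination
    radius: float = 20.0           # m target turn radius
    duration: float = 1.5          # s
    rate: float = 50.0             # Hz sample rate of the synthetic data
    noise_deg: float = 1.0         # SD of additive angular noise
    seed: int = 0
    direction: float = 1.0         # +1 turn left, -1 turn right

    def validate(self):
        if self.rate <= 0:
            raise FixtureError("sample rate must be > 0")
        if self.noise_deg < 0:
            raise FixtureError("noise SD must be >= 0")
        lean = np.arctan2(self.speed ** 2, mc.GRAVITY * self.radius)
        if lean > 1.1:
            raise FixtureError(
                f"target radius {self.radius} m is too small for {self.speed} m/s "
                f"(required lean {np.rad2deg(lean):.0f} deg)"
            )


def _plane_basis(snow: SnowPlane):
    n = snow.normal
    up = np.array([0.0, 0.0, 1.0])
    e1 = up - np.dot(up, n) * n
    e1 = -e1 / np.linalg.norm(e1) if np.linalg.norm(e1) > 1e-12 else np.array([1.0, 0, 0])
    e2 = np.cross(n, e1)
    return e1, e2, n


def turn_template(spec: SyntheticTurnSpec, system: SkiSystem) -> TrackingData:
    """Kinematic template of a turn: pelvis arc over the snow at the target
    radius in a crouched, inclined posture, with a gentle flexion cycle."""
    spec.validate()
    model = system.model
    snow = system.snow
    e1, e2, n = _plane_basis(snow)
    N = int(round(spec.duration * spec.rate)) + 1
    t = np.arange(N) / spec.rate
    omega = spec.direction * spec.speed / spec.radius
    a1 = spec.radius * np.sin(np.abs(omega) * t)
    a2 = spec.direction * spec.radius * (1 - np.cos(np.abs(omega) * t))
    yaw = omega * t
    lean = np.arctan2(spec.speed ** 2, mc.GRAVITY * spec.radius)
    u = np.minimum(t / (0.25 * spec.duration), 1.0)
    list_ang = -spec.direction * lean * (3 * u * u - 2 * u ** 3)  # smooth ramp

    slope = np.deg2rad(spec.slope_deg)
    hipf = _CROUCH["hip_flexion_r"] - 0.10 * np.sin(2 * np.pi * t / spec.duration)
    knee = _CROUCH["knee_flexion_r"] + 0.15 * np.sin(2 * np.pi * t / spec.duration)
    tilt = np.full(N, -slope) - hipf - knee  # first guess; refined below

    channels = {
        "pelvis_rotation": yaw.copy(), "pelvis_list": list_ang, "pelvis_tilt": tilt,
        "lumbar_extension": np.full(N, _CROUCH["lumbar_extension"]),
        "hip_flexion_r": hipf, "hip_flexion_l": hipf,
        "knee_flexion_r": knee, "knee_flexion_l": knee,
    }
    channels = {k: v for k, v in channels.items() if k in model.coord_names}

    # Align the SKIS (not the pelvis) with the path: with large lean and
    # flexion the chained joint rotations couple into ski yaw and pitch, so
    # solve numerically, per node, for the pelvis rotation and tilt that put
    # the ski long axis on the heading and parallel to the snow plane.
    ski_body = next(b for b, s in enumerate(model.segments)
                    if s.meta.get("ski_segment"))

    def ski_axis(ch):
        Q = np.zeros((N, model.n_q))
        for name, vals in ch.items():
            Q[:, model.coord_index(name)] = vals
        kin = mc.body_kinematics(model, Q)
        return kin.R[:, ski_body, :, 0]

    if "pelvis_rotation" in channels and "pelvis_tilt" in channels:
        for _ in range(3):
            ax = ski_axis(channels)
            d_yaw = yaw - np.arctan2(ax @ e2, ax @ e1)
            channels["pelvis_rotation"] = channels["pelvis_rotation"] + d_yaw
            # sign-agnostic bisection on tilt for zero ski pitch
            lo_t = channels["pelvis_tilt"] - 0.6
            hi_t = channels["pelvis_tilt"] + 0.6
            channels["pelvis_tilt"] = lo_t
            p_lo = ski_axis(channels) @ n
            for _ in range(25):
                mid_t = 0.5 * (lo_t + hi_t)
                channels["pelvis_tilt"] = mid_t
                p_mid = ski_axis(channels) @ n
                same = np.sign(p_mid) == np.sign(p_lo)
                lo_t = np.where(same, mid_t, lo_t)
                p_lo = np.where(same, p_mid, p_lo)
                hi_t = np.where(same, hi_t, mid_t)
            channels["pelvis_tilt"] = 0.5 * (lo_t + hi_t)

    # place the pelvis, per node, so that the static penetration-force
    # balance holds: posture changes (lean ramp, flexion cycle) move the
    # feet relative to the pelvis, and the engagement depth that carries the
    # skier's weight depends on how many edges touch and how edged they are
    Q = np.zeros((N, model.n_q))
    for name, vals in channels.items():
        Q[:, model.coord_index(name)] = vals
    kin = mc.body_kinematics(model, Q)
    edge_h, edge_kg = [], []
    cp = system.contact
    for b, seg in enumerate(model.segments):
        if not seg.meta.get("ski_segment"):
            continue
        theta = np.arcsin(np.clip(np.linalg.norm(
            np.cross(kin.R[:, b, :, 2], n), axis=-1), 0, 1))
        mid = kin.p[:, b] + np.einsum("nij,j->ni", kin.R[:, b], np.asarray(seg.com, float))
        for side in (+1.0, -1.0):
            off = np.array([0.0, side * seg.meta["half_width"], 0.0])
            edge = mid + np.einsum("nij,j->ni", kin.R[:, b], off)
            edge_h.append(snow.height_above(edge))
            edge_kg.append(cp.k_p * seg.meta["seg_length"] * cp.g_theta(theta))
    edge_h = np.stack(edge_h, axis=1)    # (N, n_edges)
    edge_kg = np.stack(edge_kg, axis=1)
    target = model.total_mass * mc.GRAVITY * np.cos(slope)
    min_h = np.min(edge_h, axis=1)
    lo, hi = -min_h - 0.3, -min_h + 0.1
    for _ in range(50):  # bisection: total Fp(shift) is monotone decreasing
        mid_s = 0.5 * (lo + hi)
        d = -(edge_h + mid_s[:, None])
        tot = np.sum(edge_kg * np.maximum(d, 0.0), axis=1)
        hi = np.where(tot < target, mid_s, hi)
        lo = np.where(tot >= target, mid_s, lo)
    shift = 0.5 * (lo + hi)

    pos = (snow.point[None, :] + a1[:, None] * e1 + a2[:, None] * e2
           + shift[:, None] * n)
    channels["pelvis_tx"] = pos[:, 0]
    channels["pelvis_ty"] = pos[:, 1]
    channels["pelvis_tz"] = pos[:, 2]
    return TrackingData(t, channels)


def _solve_template(system, template, weights, n_nodes, options) -> Solution:
    """Track a kinematic template, pinning the initial pose and rates to it
    (an unpinned problem can 'escape' the snow ballistically)."""
    problem = TrackingProblem(system, template, weights, n_nodes=n_nodes,
                              q_ref=dict(_CROUCH))
    z0 = initial_guess(problem, "interpolate_data")
    # anchor the whole initial state (pose, rates, fiber equilibria,
    # activations): the first collocation interval starts at node 1, so an
    # unanchored node 0 is otherwise free to take non-physical values
    pin = z0.reshape(problem.n_nodes, -1)[0][: system.n_x].copy()
    wpin = np.concatenate([np.full(2 * system.n_q, 1e3),
                           np.full(2 * system.n_mus, 10.0)])
    problem = TrackingProblem(system, template, weights, n_nodes=n_nodes,
                              q_ref=dict(_CROUCH), x0_pin=pin, x0_pin_weight=wpin)
    return solve_tracking(problem, z0, options)


def synthesize_turn(spec: SyntheticTurnSpec, system: SkiSystem,
                    n_nodes: int | None = None,
                    weights: ObjectiveWeights | None = None,
                    solver_options: dict | None = None):
    """Generate a dynamically consistent turn plus noisy tracking data.

    Solves a tracking problem toward the kinematic turn template; the
    optimum is the 'truth' solution (its states satisfy the implicit
    dynamics at every node).  Seeded Gaussian angular noise is
    then added to the skier's angle channels to produce the synthetic
    measurement data.  Returns ``(truth, noisy_data)``.
    """
    spec.validate()
    template = turn_template(spec, system)
    opts = dict(max_iter=100)
    opts.update(solver_options or {})
    truth = _solve_template(system, template, weights or ObjectiveWeights(), n_nodes, opts)
    if truth.max_residual > 1e-4:
        raise FixtureError(
            f"turn synthesis did not reach dynamic consistency "
            f"(status {truth.status}, residual {truth.max_residual:.2e})"
        )
    noisy = make_tracking_data(truth, system, noise_deg=spec.noise_deg, seed=spec.seed)
    return truth, noisy


def make_tracking_data(truth: Solution, system: SkiSystem, noise_deg: float = 1.0,
                       seed: int = 0) -> TrackingData:
    """Skier-DOF channels sampled from a solution, with additive angular noise.

    Noise is i.i.d. Gaussian on angle channels only; pelvis translations are
    returned noise-free (their measurement error structure is different and
    off by default).
    """
    model = system.model
    rng = np.random.default_rng(seed)
    sd = np.deg2rad(noise_deg)
    channels = {}
    for name in model.coord_names:
        if "_bend" in name or name.startswith(("l_ski", "r_ski")):
            continue
        vals = truth.states[:, system.state_index(name)].copy()
        if not name.startswith("pelvis_t"):
            vals = vals + rng.normal(0.0, sd, size=vals.shape)
        channels[name] = vals
    return TrackingData(np.asarray(truth.times, float).copy(), channels)


def make_schuss_reference(system: SkiSystem, speed: float = 12.0,
                          duration: float = 1.0, rate: float = 50.0,
                          solver_options: dict | None = None) -> Solution:
    """A dynamically consistent straight fall-line run (schuss).

    Used as the canonical initial-guess maneuver: zero lateral deviation,
    crouched posture, constant heading.
    """
    # a huge target radius degenerates the arc to the fall line
    template = turn_template(
        SyntheticTurnSpec(speed=speed, slope_deg=np.rad2deg(system.snow.inclination),
                          radius=1e4, duration=duration, rate=rate, noise_deg=0.0),
        system,
    )
    opts = dict(max_iter=100)
    opts.update(solver_options or {})
    sol = _solve_template(system, template, ObjectiveWeights(), None, opts)
    if sol.max_residual > 1e-4:
        raise FixtureError(
            f"schuss synthesis not dynamically consistent (res {sol.max_residual:.2e})"
        )
    return sol
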
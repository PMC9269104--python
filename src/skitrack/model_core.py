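"""Skier and ski multibody models and their implicit equations of motion.

The mechanical system is a tree of rigid segments connected by joints
(free 6-DOF, ball 3-DOF, revolute, or locked).  Dynamics are evaluated in
implicit form: :func:`inverse_dynamics` returns the generalized force
``tau_id(q, qd, qdd)`` required to realize an acceleration, so the equation of
motion residual is ``tau_id - tau_applied`` — zero exactly on physical
motions.  This implicit formulation is what the collocation transcription
constrains at every node.

Implementation notes
--------------------
* All evaluation routines broadcast over arbitrary leading batch axes of
  ``q`` (time nodes), and preserve complex dtype so the whole pipeline can be
  differentiated by complex-step perturbation.
* Ball and free joints are parameterized by an ordered sequence of fixed unit
  rotation axes (Rodrigues composition).  Choosing anatomical axes directly
  encodes the sign conventions used for reported joint angles and moments
  (hip flexion/adduction/internal rotation, knee extension and ankle
  dorsiflexion positive).
* Generalized forces are obtained by projecting per-body Newton-Euler force
  and moment balances onto the world-frame coordinate axes (equivalent to a
  backward recursion over the tree, but expressible as batched einsums).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .rotations import axis_angle, cross

__all__ = [
    "ModelError",
    "Segment",
    "Joint",
    "SkiSpec",
    "MultibodyModel",
    "SystemState",
    "Controls",
    "Kinematics",
    "build_skier_model",
    "build_ski_model",
    "assemble_full_model",
    "graft_model",
    "body_kinematics",
    "inverse_dynamics",
    "mass_matrix",
    "bias_force",
    "wrench_to_generalized",
    "dynamics_residual",
    "ski_joint_passive_moment",
    "forward_simulate",
    "implicit_euler_step",
]

GRAVITY = 9.81


class ModelError(ValueError):
    """Raised for inconsistent model configuration or assembly."""


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------

@dataclass
class Segment:
    """A rigid segment: mass, inertia about the COM (body frame), COM offset."""

    name: str
    mass: float
    inertia: np.ndarray  # (3,3) about COM, body frame
    com: np.ndarray      # (3,) body frame offset of COM from segment origin
    length: float = 0.0
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mass < 0:
            raise ModelError(f"segment {self.name!r}: mass must be >= 0, got {self.mass}")
        if self.length < 0:
            raise ModelError(f"segment {self.name!r}: length must be >= 0, got {self.length}")
        I = np.asarray(self.inertia, float)
        if I.shape != (3, 3):
            raise ModelError(f"segment {self.name!r}: inertia must be 3x3")
        if not np.allclose(I, I.T, atol=1e-9):
            raise ModelError(f"segment {self.name!r}: inertia must be symmetric")
        if np.min(np.linalg.eigvalsh(I)) < -1e-12:
            raise ModelError(f"segment {self.name!r}: inertia must be positive semidefinite")


@dataclass
class Joint:
    """Joint i connects ``parent`` (segment index, -1 = world) to segment i.

    ``anchor`` is the joint location in the parent frame.  ``axes`` holds one
    unit rotation axis per rotational coordinate (in the joint's fixed frame,
    which coincides with the parent frame at q = 0).  A 'free' joint has three
    translation coordinates (along the parent axes) followed by its rotation
    axes; 'weld' has none.
    """

    name: str
    jtype: str  # 'free' | 'ball' | 'revolute' | 'weld'
    parent: int
    anchor: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    coord_names: list = field(default_factory=list)
    q_index: int = -1  # filled by finalize()

    @property
    def n_trans(self) -> int:
        return 3 if self.jtype == "free" else 0

    @property
    def n_rot(self) -> int:
        return len(self.axes)

    @property
    def n_coords(self) -> int:
        return self.n_trans + self.n_rot

    def validate(self) -> None:
        if self.jtype not in ("free", "ball", "revolute", "weld"):
            raise ModelError(f"joint {self.name!r}: unknown type {self.jtype!r}")
        axes = np.atleast_2d(self.axes) if len(self.axes) else np.zeros((0, 3))
        expected = {"free": 3, "ball": 3, "revolute": 1, "weld": 0}[self.jtype]
        if axes.shape[0] != expected:
            raise ModelError(
                f"joint {self.name!r}: type {self.jtype!r} needs {expected} rotation "
                f"axes, got {axes.shape[0]}"
            )
        for k in range(axes.shape[0]):
            n = np.linalg.norm(axes[k])
            if abs(n - 1.0) > 1e-9:
                raise ModelError(f"joint {self.name!r}: axis {k} is not unit-norm")
        if len(self.coord_names) != self.n_coords:
            raise ModelError(f"joint {self.name!r}: coord_names length mismatch")


@dataclass
class SkiSpec:
    """Geometry, mass and joint stiffness of one segmented ski.

    Defaults describe a competition giant-slalom ski: 2.02 m long, 2.1 kg,
    32 m sidecut radius, discretized into 7 rear + 1 center + 10 front
    segments joined by transverse revolute (bending) joints.  The per-joint
    bending stiffness profile is stiffer near the binding and softer toward
    tip and tail; it is a plausible default, configurable, not bench-validated.
    """

    length: float = 2.02
    mass: float = 2.1
    sidecut_radius: float = 32.0
    n_rear: int = 7
    n_center: int = 1
    n_front: int = 10
    waist_width: float = 0.065
    stiffness_center: float = 2000.0   # N*m/rad
    stiffness_tip: float = 300.0       # N*m/rad
    damping_ratio: float = 0.03        # c = ratio * k * 1 s

    @property
    def n_segments(self) -> int:
        return self.n_rear + self.n_center + self.n_front

    def validate(self) -> None:
        if self.length <= 0:
            raise ModelError(f"ski: length must be > 0, got {self.length}")
        if self.mass <= 0:
            raise ModelError(f"ski: mass must be > 0, got {self.mass}")
        if self.sidecut_radius <= self.length / 2:
            raise ModelError("ski: sidecut_radius must exceed half the ski length")
        if min(self.n_rear, self.n_center, self.n_front) < 1:
            raise ModelError("ski: segment counts must each be >= 1")
        if self.stiffness_center < 0 or self.stiffness_tip < 0 or self.damping_ratio < 0:
            raise ModelError("ski: stiffness and damping must be >= 0")

    def joint_stiffness(self, xi: float) -> float:
        """Bending stiffness at longitudinal station ``xi`` (m from waist)."""
        u = min(abs(xi) / (self.length / 2), 1.0)
        return self.stiffness_center + (self.stiffness_tip - self.stiffness_center) * u * u

    def half_width(self, xi: float) -> float:
        """Running edge half-width from the sidecut arc (m)."""
        R = self.sidecut_radius
        xi = min(abs(xi), self.length / 2)
        return self.waist_width / 2 + (R - np.sqrt(R * R - xi * xi))


@dataclass
class SystemState:
    """Full musculoskeletal state x = (q, qdot, s, a).

    ``s`` are projected muscle-fiber lengths (contractile-element length along
    the tendon, m) and ``a`` the activations; both empty for a bare skeleton.
    """

    q: np.ndarray
    qdot: np.ndarray
    s: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class Controls:
    """Neural excitations e in [0, 1], one per muscle."""

    e: np.ndarray


class MultibodyModel:
    """An ordered tree of segments and joints with bookkeeping for dynamics."""

    def __init__(self, name: str = "model", gravity: Sequence[float] = (0.0, 0.0, -GRAVITY)):
        self.name = name
        self.gravity = np.asarray(gravity, float)
        self.segments: list[Segment] = []
        self.joints: list[Joint] = []
        self.n_q = 0
        self.coord_names: list[str] = []
        self.coord_kind: list[str] = []   # 't' | 'r'
        self.coord_body: np.ndarray | None = None   # body moved by each coord
        self.descendants: np.ndarray | None = None  # (n_q, n_bodies) bool

    # -- construction ------------------------------------------------------

    def add_body(self, segment: Segment, joint: Joint) -> int:
        if joint.parent >= len(self.segments):
            raise ModelError(
                f"joint {joint.name!r}: dangling parent index {joint.parent}"
            )
        self.segments.append(segment)
        self.joints.append(joint)
        return len(self.segments) - 1

    def finalize(self) -> "MultibodyModel":
        self.n_q = 0
        self.coord_names = []
        self.coord_kind = []
        coord_body = []
        for i, (seg, jnt) in enumerate(zip(self.segments, self.joints)):
            seg.validate()
            jnt.validate()
            jnt.q_index = self.n_q
            self.n_q += jnt.n_coords
            self.coord_names.extend(jnt.coord_names)
            self.coord_kind.extend(["t"] * jnt.n_trans + ["r"] * jnt.n_rot)
            coord_body.extend([i] * jnt.n_coords)
        if len(set(self.coord_names)) != len(self.coord_names):
            raise ModelError("duplicate coordinate names in model")
        self.coord_body = np.asarray(coord_body, int)
        nb = len(self.segments)
        # ancestor bookkeeping: desc[k, b] True if coordinate k moves body b
        parent = np.array([j.parent for j in self.joints])
        desc = np.zeros((self.n_q, nb), bool)
        for b in range(nb):
            a = b
            while a >= 0:
                jnt = self.joints[a]
                desc[jnt.q_index:jnt.q_index + jnt.n_coords, b] = True
                a = parent[a]
        self.descendants = desc
        return self

    # -- queries -----------------------------------------------------------

    @property
    def n_bodies(self) -> int:
        return len(self.segments)

    def coord_index(self, name: str) -> int:
        return self.coord_names.index(name)

    def body_index(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise ModelError(f"no segment named {name!r}")

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    def summary(self) -> "object":
        """Model summary as a pandas DataFrame (one row per segment)."""
        import pandas as pd

        rows = []
        for seg, jnt in zip(self.segments, self.joints):
            rows.append(
                dict(
                    segment=seg.name,
                    mass=seg.mass,
                    length=seg.length,
                    joint=jnt.name,
                    joint_type=jnt.jtype,
                    parent=self.segments[jnt.parent].name if jnt.parent >= 0 else "world",
                    coords=",".join(jnt.coord_names),
                )
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

@dataclass
class Kinematics:
    """World-frame pose, velocity and acceleration of every body.

    Arrays are shaped (batch..., n_bodies, 3[, 3]).  ``axis_w``/``anchor_w``
    give, per generalized coordinate, the world direction of its motion axis
    and (for rotations) the world position of its joint anchor — the data
    needed to project wrenches onto generalized forces.
    """

    R: np.ndarray
    p: np.ndarray
    omega: np.ndarray
    v: np.ndarray
    omegadot: np.ndarray
    a: np.ndarray
    com: np.ndarray
    acom: np.ndarray
    axis_w: np.ndarray
    anchor_w: np.ndarray


def _result_dtype(*arrays):
    return complex if any(np.iscomplexobj(a) for a in arrays) else float


def body_kinematics(model: MultibodyModel, q, qd=None, qdd=None) -> Kinematics:
    """Forward kinematics with velocities and accelerations (batched).

    ``q`` has shape (..., n_q); missing ``qd``/``qdd`` default to zero.
    """
    q = np.asarray(q)
    if q.shape[-1] != model.n_q:
        raise ModelError(f"q has {q.shape[-1]} coords, model has {model.n_q}")
    if qd is None:
        qd = np.zeros_like(q)
    if qdd is None:
        qdd = np.zeros_like(q)
    qd = np.asarray(qd)
    qdd = np.asarray(qdd)
    dt = _result_dtype(q, qd, qdd)
    batch = q.shape[:-1]
    nb = model.n_bodies

    def zeros(*shape):
        return np.zeros(batch + shape, dtype=dt)

    R = zeros(nb, 3, 3)
    p = zeros(nb, 3)
    om = zeros(nb, 3)
    v = zeros(nb, 3)
    omd = zeros(nb, 3)
    a = zeros(nb, 3)
    com = zeros(nb, 3)
    acom = zeros(nb, 3)
    axis_w = zeros(model.n_q, 3)
    anchor_w = zeros(model.n_q, 3)

    eyeb = np.broadcast_to(np.eye(3), batch + (3, 3))

    for i, (seg, jnt) in enumerate(zip(model.segments, model.joints)):
        if jnt.parent >= 0:
            Rp, pp = R[..., jnt.parent, :, :], p[..., jnt.parent, :]
            omp, vp = om[..., jnt.parent, :], v[..., jnt.parent, :]
            omdp, ap = omd[..., jnt.parent, :], a[..., jnt.parent, :]
        else:
            Rp = eyeb.astype(dt)
            pp = zeros(3)
            omp = zeros(3)
            vp = zeros(3)
            omdp = zeros(3)
            ap = zeros(3)

        k0 = jnt.q_index
        anchor = np.asarray(jnt.anchor, float)
        r_off = np.einsum("...ij,j->...i", Rp, anchor)

        # translation part (free joints): coordinates along parent axes
        if jnt.n_trans:
            t_loc = q[..., k0:k0 + 3]
            td_loc = qd[..., k0:k0 + 3]
            tdd_loc = qdd[..., k0:k0 + 3]
            t_w = np.einsum("...ij,...j->...i", Rp, t_loc)
            td_w = np.einsum("...ij,...j->...i", Rp, td_loc)
            tdd_w = np.einsum("...ij,...j->...i", Rp, tdd_loc)
            for m in range(3):
                axis_w[..., k0 + m, :] = Rp[..., :, m]
        else:
            t_w = td_w = tdd_w = zeros(3)
        kr = k0 + jnt.n_trans

        # rotation part: Rodrigues composition over the joint's axis sequence
        R_rel = eyeb.astype(dt)
        om_rel = zeros(3)          # relative angular velocity, parent frame
        omd_rel = zeros(3)         # relative angular acceleration, parent frame
        for m in range(jnt.n_rot):
            ax = jnt.axes[m]
            e_m = np.einsum("...ij,j->...i", R_rel, np.asarray(ax, float)).astype(dt)
            qdm = qd[..., kr + m, None]
            qddm = qdd[..., kr + m, None]
            # product-rule: e_m itself rotates with the preceding rotations
            omd_rel = omd_rel + qddm * e_m + qdm * cross(om_rel, e_m)
            om_rel = om_rel + qdm * e_m
            axis_w[..., kr + m, :] = np.einsum("...ij,...j->...i", Rp, e_m)
            R_rel = R_rel @ axis_angle(ax, q[..., kr + m])

        joint_pos = pp + r_off + t_w
        for m in range(jnt.n_coords):
            anchor_w[..., k0 + m, :] = joint_pos

        Ri = Rp @ R_rel
        om_rel_w = np.einsum("...ij,...j->...i", Rp, om_rel)
        omi = omp + om_rel_w
        omdi = omdp + np.einsum("...ij,...j->...i", Rp, omd_rel) + cross(omp, om_rel_w)

        lever = r_off + t_w
        vi = vp + cross(omp, lever) + td_w
        ai = (
            ap
            + cross(omdp, lever)
            + cross(omp, cross(omp, lever))
            + 2.0 * cross(omp, td_w)
            + tdd_w
        )

        R[..., i, :, :] = Ri
        p[..., i, :] = joint_pos
        om[..., i, :] = omi
        v[..., i, :] = vi
        omd[..., i, :] = omdi
        a[..., i, :] = ai
        c_off = np.einsum("...ij,j->...i", Ri, np.asarray(seg.com, float))
        com[..., i, :] = joint_pos + c_off
        acom[..., i, :] = ai + cross(omdi, c_off) + cross(omi, cross(omi, c_off))

    return Kinematics(R, p, om, v, omd, a, com, acom, axis_w, anchor_w)


# --------------------------------------------------------------------------
# inverse dynamics (implicit equations of motion)
# --------------------------------------------------------------------------

def _project_generalized(model: MultibodyModel, kin: Kinematics, F, N):
    """Project per-body net forces F and COM moments N onto the coordinates.

    tau_k = sum over bodies b moved by k of
        axis_k . F_b                          (translation coordinate)
        axis_k . (N_b + (com_b - anchor_k) x F_b)   (rotation coordinate)
    """
    desc = model.descendants
    kind_r = np.array([k == "r" for k in model.coord_kind])
    ax = kin.axis_w                      # (..., nq, 3)
    # translation coordinates
    tau = np.einsum("...kd,...bd,kb->...k", ax, F, desc & ~kind_r[:, None])
    # rotation coordinates: a.(N) + (a x (c - x)) . F
    tau = tau + np.einsum("...kd,...bd,kb->...k", ax, N, desc & kind_r[:, None])
    rel = kin.com[..., None, :, :] - kin.anchor_w[..., :, None, :]  # (...,nq,nb,3)
    w = cross(np.broadcast_to(ax[..., :, None, :], rel.shape), rel)
    tau = tau + np.einsum("...kbd,...bd,kb->...k", w, F, desc & kind_r[:, None])
    return tau


def inverse_dynamics(
    model: MultibodyModel,
    q,
    qd=None,
    qdd=None,
    ext_force=None,
    ext_torque=None,
    gravity: bool = True,
    kin: Kinematics | None = None,
):
    """Generalized force tau(q, qd, qdd) required by the equations of motion.

    ``ext_force``/``ext_torque``: optional per-body external wrench, world
    frame, (..., n_bodies, 3); force acts at the body origin with the given
    accompanying torque.  The returned tau satisfies
    ``tau = M(q) qdd + c(q, qd) - tau_ext``.
    """
    if kin is None:
        kin = body_kinematics(model, q, qd, qdd)
    dt = kin.acom.dtype
    masses = np.array([s.mass for s in model.segments])
    g = model.gravity if gravity else np.zeros(3)
    F = masses[:, None] * (kin.acom - g)                       # (..., nb, 3)
    F = F.astype(dt)
    # rotational balance about COM: I_w omdot + om x (I_w om)
    Ib = np.stack([np.asarray(s.inertia, float) for s in model.segments])
    Iw = np.einsum("...bij,bjk,...blk->...bil", kin.R, Ib, kin.R)
    N = np.einsum("...bij,...bj->...bi", Iw, kin.omegadot) + cross(
        kin.omega, np.einsum("...bij,...bj->...bi", Iw, kin.omega)
    )
    if ext_force is not None:
        ext_force = np.asarray(ext_force)
        F = F - ext_force
        # the external force acts at the body origin: moment about COM
        N = N - cross(kin.p - kin.com, ext_force)
    if ext_torque is not None:
        N = N - np.asarray(ext_torque)
    return _project_generalized(model, kin, F, N)


def mass_matrix(model: MultibodyModel, q):
    """Dense joint-space mass matrix M(q) via unit-acceleration sweeps."""
    q = np.asarray(q, float)
    n = model.n_q
    qdd = np.eye(n)
    qb = np.broadcast_to(q, (n,) + q.shape)
    M = inverse_dynamics(model, qb, np.zeros_like(qb), qdd, gravity=False)
    return np.moveaxis(M, 0, -1)


def bias_force(model: MultibodyModel, q, qd, gravity: bool = True):
    """Velocity and gravity terms c(q, qd) = ID(q, qd, 0)."""
    return inverse_dynamics(model, q, qd, np.zeros_like(np.asarray(q)), gravity=gravity)


def wrench_to_generalized(model: MultibodyModel, q, body: int, force, point=None, torque=None):
    """Map a world wrench on one body to generalized forces (J^T w)."""
    kin = body_kinematics(model, q)
    nb = model.n_bodies
    F = np.zeros(np.shape(q)[:-1] + (nb, 3))
    N = np.zeros_like(F)
    force = np.asarray(force, float)
    F[..., body, :] = -force
    if point is not None:
        lever = np.asarray(point, float) - kin.com[..., body, :]
        N[..., body, :] -= cross(lever, force)
    else:
        N[..., body, :] -= cross(kin.p[..., body, :] - kin.com[..., body, :], force)
    if torque is not None:
        N[..., body, :] -= np.asarray(torque, float)
    return -_project_generalized(model, kin, F, N)


def dynamics_residual(model: MultibodyModel, x: SystemState, xdot: SystemState, applied=None):
    """Implicit multibody residual f(x, xdot) for a bare skeleton.

    Stacks the kinematic identity ``xdot.q - x.qdot`` with the force balance
    ``ID(q, qdot, xdot.qdot) - tau_applied``; zero iff the motion satisfies
    the equations of motion under the given generalized applied forces.
    """
    q, qdot = np.asarray(x.q), np.asarray(x.qdot)
    if q.shape != qdot.shape or q.shape[-1] != model.n_q:
        raise ModelError("state dimensions do not match the model")
    r_kin = np.asarray(xdot.q) - qdot
    tau_id = inverse_dynamics(model, q, qdot, np.asarray(xdot.qdot))
    if applied is None:
        applied = 0.0
    return np.concatenate([r_kin, tau_id - applied], axis=-1)


# --------------------------------------------------------------------------
# passive ski joint moments
# --------------------------------------------------------------------------

def ski_joint_passive_moment(deflection, rate, k, c):
    """Rotational spring-damper moment of a ski bending joint.

    M = -k*deflection - c*rate, applied equal-and-opposite across the joint.
    """
    if np.real(k) < 0 or np.real(c) < 0:
        raise ModelError("ski joint stiffness and damping must be >= 0")
    return -k * deflection - c * rate


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _box_inertia(m, lx, ly, lz):
    return m / 12.0 * np.diag([ly * ly + lz * lz, lx * lx + lz * lz, lx * lx + ly * ly])


#: default anthropometry: literature-style segment mass fractions and
#: height-relative lengths; arms and head are folded into the trunk segment
#: in a fixed forward posture (the skier model's arms are locked).
_SEG_FRACTIONS = {
    "pelvis": 0.112,
    "trunk": 0.4908,   # thorax + head + both arms in fixed posture
    "thigh": 0.1416,
    "shank": 0.0433,
    "foot": 0.0137,
}

_AX_X = np.array([1.0, 0.0, 0.0])
_AX_Y = np.array([0.0, 1.0, 0.0])
_AX_Z = np.array([0.0, 0.0, 1.0])


def build_skier_model(config: Optional[dict] = None) -> MultibodyModel:
    """Build the skier skeleton (default: 19 DOFs).

    World frame: x forward (downhill), y left, z up; gravity -z.  The skier's
    coordinates are 6 between pelvis and ground, 3 at the lumbar joint, and
    3 + 1 + 1 at each hip, knee and ankle.  Positive directions follow the
    reporting convention: hip flexion/adduction/internal rotation, knee
    extension, ankle dorsiflexion, lumbar extension/lateral bend/left
    rotation.  ``config['locked']`` names coordinates to remove (the ski
    boot already locks subtalar and toe articulation — those joints are not
    modelled as coordinates at all).
    """
    cfg = dict(config or {})
    mass = float(cfg.pop("body_mass", 75.0))
    height = float(cfg.pop("height", 1.78))
    locked = set(cfg.pop("locked", ()))
    gravity = np.asarray(cfg.pop("gravity", (0.0, 0.0, -GRAVITY)), float)
    if cfg:
        raise ModelError(f"unknown skier config keys: {sorted(cfg)}")
    if mass <= 0:
        raise ModelError(f"skier config: body_mass must be > 0, got {mass}")
    if height <= 0:
        raise ModelError(f"skier config: height must be > 0, got {height}")

    s = height / 1.78
    thigh_len, shank_len = 0.430 * s, 0.425 * s
    trunk_len, foot_len = 0.55 * s, 0.26 * s
    hip_half = 0.085 * s
    m = {k: f * mass for k, f in _SEG_FRACTIONS.items()}

    model = MultibodyModel("skier", gravity)

    def maybe_axes(pairs):
        """Filter (axis, name) pairs by the locked set."""
        kept = [(a, n) for a, n in pairs if n not in locked]
        return np.array([a for a, _ in kept]).reshape(-1, 3), [n for _, n in kept]

    # pelvis: free joint to ground (6 DOF); rotation order yaw-roll-pitch
    rot_axes, rot_names = maybe_axes(
        [(_AX_Z, "pelvis_rotation"), (_AX_X, "pelvis_list"), (-_AX_Y, "pelvis_tilt")]
    )
    trans = [n for n in ("pelvis_tx", "pelvis_ty", "pelvis_tz") if n not in locked]
    if len(trans) != 3 or len(rot_names) != 3:
        # locking part of the floating base is not supported; lock all or none
        if trans or rot_names:
            raise ModelError("pelvis-ground coordinates can only be locked all together")
        root = Joint("ground_pelvis", "weld", -1, np.zeros(3))
    else:
        root = Joint(
            "ground_pelvis", "free", -1, np.zeros(3), rot_axes, trans + rot_names
        )
    pelvis = Segment(
        "pelvis", m["pelvis"], _box_inertia(m["pelvis"], 0.20 * s, 0.30 * s, 0.15 * s),
        np.array([0.0, 0.0, 0.03 * s]),
        0.15 * s,
    )
    ip = model.add_body(pelvis, root)

    # lumbar joint + trunk (head and arms folded in, slightly forward COM)
    axes, names = maybe_axes(
        [(-_AX_Y, "lumbar_extension"), (_AX_X, "lumbar_bending"), (_AX_Z, "lumbar_rotation")]
    )
    trunk = Segment(
        "trunk", m["trunk"],
        _box_inertia(m["trunk"], 0.30 * s, 0.35 * s, trunk_len) * 1.4,
        np.array([0.03 * s, 0.0, 0.45 * trunk_len]),
        trunk_len,
    )
    jtype = "weld" if len(names) == 0 else ("revolute" if len(names) == 1 else "ball")
    model.add_body(trunk, Joint("lumbar", jtype, ip, np.array([0.0, 0.0, 0.12 * s]), axes, names))

    for side, sgn in (("r", -1.0), ("l", +1.0)):
        # hip: flexion, adduction, internal rotation (mirrored axes)
        axes, names = maybe_axes(
            [
                (-_AX_Y, f"hip_flexion_{side}"),
                (-sgn * _AX_X, f"hip_adduction_{side}"),
                (-sgn * _AX_Z, f"hip_rotation_{side}"),
            ]
        )
        thigh = Segment(
            f"thigh_{side}", m["thigh"],
            _box_inertia(m["thigh"], 0.12 * s, 0.12 * s, thigh_len),
            np.array([0.0, 0.0, -0.433 * thigh_len]),
            thigh_len,
        )
        jtype = "weld" if len(names) == 0 else ("revolute" if len(names) == 1 else "ball")
        ith = model.add_body(
            thigh, Joint(f"hip_{side}", jtype, ip, np.array([0.0, sgn * hip_half, 0.0]), axes, names)
        )

        # knee: single hinge; coordinate positive toward extension, so the
        # flexed posture has negative angle (reporting convention)
        axes, names = maybe_axes([(-_AX_Y, f"knee_flexion_{side}")])
        shank = Segment(
            f"shank_{side}", m["shank"],
            _box_inertia(m["shank"], 0.09 * s, 0.09 * s, shank_len),
            np.array([0.0, 0.0, -0.433 * shank_len]),
            shank_len,
        )
        jtype = "weld" if len(names) == 0 else "revolute"
        ish = model.add_body(
            shank, Joint(f"knee_{side}", jtype, ith, np.array([0.0, 0.0, -thigh_len]), axes, names)
        )

        # ankle: dorsiflexion positive (subtalar and mtp are locked by the boot)
        axes, names = maybe_axes([(-_AX_Y, f"ankle_dorsiflexion_{side}")])
        foot = Segment(
            f"foot_{side}", m["foot"],
            _box_inertia(m["foot"], foot_len, 0.08 * s, 0.07 * s),
            np.array([0.05 * s, 0.0, -0.05 * s]),
            foot_len,
            meta={"sole_anchor": np.array([0.02 * s, 0.0, -0.09 * s])},
        )
        jtype = "weld" if len(names) == 0 else "revolute"
        model.add_body(
            foot, Joint(f"ankle_{side}", jtype, ish, np.array([0.0, 0.0, -shank_len]), axes, names)
        )

    return model.finalize()


def build_ski_model(spec: Optional[SkiSpec] = None) -> MultibodyModel:
    """Build one segmented ski as a standalone model (center segment at root).

    The center segment is welded to the world (it gets welded to a boot on
    assembly); the rear and front segments chain outward through transverse
    revolute bending joints with rotational spring-dampers, giving 17
    internal DOFs for the default 18 segments.  Torsional twist is omitted.
    """
    spec = spec or SkiSpec()
    spec.validate()
    seg_len = spec.length / spec.n_segments
    seg_mass = spec.mass / spec.n_segments
    model = MultibodyModel("ski")

    def ski_segment(tag: str, xi_mid: float, com_x: float, bend_k: float | None) -> Segment:
        hw = spec.half_width(xi_mid)
        meta = {
            "ski_segment": True,
            "seg_length": seg_len,
            "half_width": hw,
            "station": xi_mid,
        }
        if bend_k is not None:
            meta["bend_stiffness"] = bend_k
            meta["bend_damping"] = spec.damping_ratio * bend_k
        return Segment(
            f"ski_{tag}", seg_mass,
            _box_inertia(seg_mass, seg_len, 2 * hw, 0.02),
            np.array([com_x, 0.0, 0.0]), seg_len, meta,
        )

    # center block: origin/waist at the middle of the block, welded chain
    half_block = spec.n_center * seg_len / 2
    prev = model.add_body(
        ski_segment("c1", -half_block + seg_len / 2, 0.0, None),
        Joint("ski_root", "weld", -1, np.zeros(3)),
    )
    for j in range(2, spec.n_center + 1):
        xi = -half_block + (j - 0.5) * seg_len
        prev = model.add_body(
            ski_segment(f"c{j}", xi, seg_len / 2, None),
            Joint(f"ski_cweld{j}", "weld", prev, np.array([seg_len, 0.0, 0.0])),
        )
    # NOTE: center-block origin is the first center segment's midpoint, so
    # COM offsets above are relative to that (exact for n_center = 1).

    def chain(count: int, direction: float, tag: str, start_parent: int, start_x: float):
        parent = start_parent
        for j in range(1, count + 1):
            xi_joint = direction * (half_block + (j - 1) * seg_len)
            xi_mid = xi_joint + direction * seg_len / 2
            anchor_x = start_x if j == 1 else direction * seg_len
            parent = model.add_body(
                ski_segment(f"{tag}{j}", xi_mid, direction * seg_len / 2,
                            spec.joint_stiffness(xi_joint)),
                Joint(
                    f"{tag}_bend{j}", "revolute", parent,
                    np.array([anchor_x, 0.0, 0.0]),
                    np.array([[0.0, 1.0, 0.0]]), [f"ski_{tag}_bend{j}"],
                ),
            )

    last_center = spec.n_center - 1
    chain(spec.n_front, +1.0, "front", last_center, seg_len / 2)
    chain(spec.n_rear, -1.0, "rear", 0, -seg_len / 2)
    model.ski_spec = spec
    return model.finalize()


def graft_model(
    host: MultibodyModel,
    sub: MultibodyModel,
    parent_body: int,
    anchor,
    prefix: str = "",
) -> list[int]:
    """Graft ``sub``'s tree onto ``host`` at ``parent_body`` (weld at root).

    Returns the new body indices.  The sub-model root joint is replaced by a
    weld located at ``anchor`` in the parent body frame.
    """
    offset = host.n_bodies
    new_indices = []
    for i, (seg, jnt) in enumerate(zip(sub.segments, sub.joints)):
        seg2 = Segment(
            prefix + seg.name, seg.mass, np.array(seg.inertia), np.array(seg.com),
            seg.length, dict(seg.meta),
        )
        if jnt.parent < 0:
            jnt2 = Joint(prefix + jnt.name, "weld", parent_body, np.asarray(anchor, float))
        else:
            jnt2 = Joint(
                prefix + jnt.name, jnt.jtype, jnt.parent + offset,
                np.array(jnt.anchor), np.array(jnt.axes),
                [prefix + n for n in jnt.coord_names],
            )
        new_indices.append(host.add_body(seg2, jnt2))
    return new_indices


def assemble_full_model(
    skier: MultibodyModel,
    ski_left: Optional[MultibodyModel] = None,
    ski_right: Optional[MultibodyModel] = None,
) -> MultibodyModel:
    """Weld ski center segments to the skier's boot soles (0 added DOFs).

    Default full model: 19 (skier) + 17 + 17 = 53 generalized coordinates.
    """
    model = MultibodyModel(
        "skier_with_skis", np.array(skier.gravity)
    )
    for seg, jnt in zip(skier.segments, skier.joints):
        model.add_body(
            Segment(seg.name, seg.mass, np.array(seg.inertia), np.array(seg.com),
                    seg.length, dict(seg.meta)),
            Joint(jnt.name, jnt.jtype, jnt.parent, np.array(jnt.anchor),
                  np.array(jnt.axes), list(jnt.coord_names)),
        )
    for side, ski in (("l", ski_left), ("r", ski_right)):
        if ski is None:
            continue
        try:
            foot = model.body_index(f"foot_{side}")
        except ModelError as err:
            raise ModelError(f"cannot attach {side} ski: {err}") from err
        if model.segments[foot].meta.get("has_ski"):
            raise ModelError(f"foot_{side} already carries a ski")
        anchor = model.segments[foot].meta.get("sole_anchor", np.zeros(3))
        idx = graft_model(model, ski, foot, anchor, prefix=f"{side}_")
        model.segments[foot].meta["has_ski"] = True
        for i in idx:
            model.segments[i].meta["ski_side"] = side
    return model.finalize()


# --------------------------------------------------------------------------
# implicit Euler forward simulation (oracle / fixture generator)
# --------------------------------------------------------------------------

class SimulationError(RuntimeError):
    """Newton iteration failed during forward simulation."""


def _complex_step_jacobian(fun: Callable, x: np.ndarray, h: float = 1e-30) -> np.ndarray:
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        xp = x.astype(complex)
        xp[j] += 1j * h
        J[:, j] = np.imag(fun(xp)) / h
    return J


def implicit_euler_step(residual_fn, x_prev, h, tol=1e-10, max_iter=50):
    """Solve f(x, (x - x_prev)/h) = 0 for x by damped Newton iteration.

    ``residual_fn(x, xdot)`` must accept complex inputs (complex-step
    Jacobian).  Returns the converged state.
    """
    x = np.array(x_prev, float)
    g = lambda z: np.asarray(residual_fn(z, (z - x_prev) / h))
    r = g(x)
    J = None
    for it in range(max_iter):
        nr = float(np.max(np.abs(r)))
        if nr < tol:
            return x
        if J is None or it % 4 == 0:
            J = _complex_step_jacobian(g, x)
        try:
            dx = np.linalg.solve(J, -np.real(r))
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -np.real(r), rcond=None)[0]
        alpha = 1.0
        for _ in range(12):
            r_new = g(x + alpha * dx)
            if np.max(np.abs(r_new)) < nr * (1 - 1e-4 * alpha) or np.max(np.abs(r_new)) < tol:
                break
            alpha *= 0.5
        x = x + alpha * dx
        r = r_new
        if alpha < 1e-3:
            J = None  # force a fresh Jacobian next pass
    if float(np.max(np.abs(r))) < 100 * tol:
        return x
    raise SimulationError(f"Newton failed: residual {np.max(np.abs(r)):.3e}")


def forward_simulate(model, x0, control_fn=None, h: float = 0.01, n_steps: int = 100,
                     tol: float = 1e-10):
    """Integrate implicit dynamics with the implicit Euler formula.

    ``model`` may be a :class:`MultibodyModel` (state [q, qdot], controls are
    generalized applied forces from ``control_fn(t, x)``) or any callable
    residual ``f(x, xdot, t)`` for test dynamics.  Returns an
    (n_steps+1, n_x) trajectory; every step satisfies the implicit Euler
    residual to ``tol``.
    """
    if h <= 0:
        raise ValueError(f"step size must be > 0, got {h}")
    x0 = np.asarray(x0, float)

    if callable(model) and not isinstance(model, MultibodyModel):
        def make_residual(t):
            return lambda x, xd: model(x, xd, t)
    else:
        nq = model.n_q

        def make_residual(t):
            def res(x, xd):
                tau = 0.0 if control_fn is None else control_fn(t, x)
                st = SystemState(x[:nq], x[nq:2 * nq])
                std = SystemState(xd[:nq], xd[nq:2 * nq])
                return dynamics_residual(model, st, std, tau)
            return res

    def take_step(x_prev, t_end, step, depth=0):
        """One implicit Euler step, halved recursively if Newton fails."""
        try:
            return implicit_euler_step(
                make_residual(t_end), x_prev, step, tol=tol
            )
        except SimulationError:
            if depth >= 5:
                raise
            x_mid = take_step(x_prev, t_end - step / 2, step / 2, depth + 1)
            return take_step(x_mid, t_end, step / 2, depth + 1)

    traj = np.empty((n_steps + 1, x0.size))
    traj[0] = x0
    for k in range(1, n_steps + 1):
        try:
            traj[k] = take_step(traj[k - 1], k * h, h)
        except SimulationError as err:
            raise SimulationError(f"step {k}: {err}") from err
    return traj
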
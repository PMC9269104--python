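"""Ski-snow contact: penetration, shear and friction forces per ski segment.

Three force types act on every ski segment in contact with the snow plane:

* a penetration force ``Fp`` along the snow normal, from an elastic
  force-penetration law in the edge's penetration depth and depth rate,
  modulated by the edging angle (the angle between the ski base plane and
  the snow surface);
* a shear force ``Fs`` in the snow plane, orthogonal to the ski edge,
  resisting lateral shearing of the penetrated edge;
* a Coulomb friction force ``Ff`` antiparallel to the segment's sliding
  velocity with constant coefficient mu = 0.1, velocity-regularized so the
  force vanishes smoothly at rest.

Contact is evaluated at both the left and right edge of each segment
midpoint: when the ski is rolled, only the lower (inside) edge penetrates,
so the edge selection is implicit and smooth in the roll angle; when the
ski is flat both edges share the load.  All laws are C1 in the state, a
requirement for the collocation optimizer, and complex-step safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._smooth import smooth_max0, smooth_norm, smooth_sat
from .model_core import Kinematics, ModelError, MultibodyModel
from .rotations import cross

__all__ = [
    "SnowPlane",
    "ContactParams",
    "ContactState",
    "edging_angle",
    "penetration_force",
    "shear_force",
    "friction_force",
    "contact_wrench",
    "ski_contact_loads",
]


@dataclass
class SnowPlane:
    """Rigid inclined snow surface: a point and a unit outward normal."""

    point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-6:
            raise ModelError(f"snow normal must be unit-norm, |n| = {n}")

    @classmethod
    def inclined(cls, inclination_rad: float, point=(0.0, 0.0, 0.0)) -> "SnowPlane":
        """Plane descending in +x with the given inclination from horizontal."""
        a = float(inclination_rad)
        return cls(np.asarray(point, float), np.array([np.sin(a), 0.0, np.cos(a)]))

    @property
    def inclination(self) -> float:
        """Slope angle from horizontal (rad)."""
        return float(np.arccos(np.clip(self.normal[2], -1.0, 1.0)))

    def height_above(self, p):
        """Signed distance of points above the plane (negative = below)."""
        return np.sum((np.asarray(p) - self.point) * self.normal, axis=-1)


@dataclass
class ContactParams:
    """Snow contact constants.

    ``k_p`` and ``k_s`` are stiffnesses per meter of edge length per meter of
    penetration depth (N/m^2).  The edging-angle factor
    ``g(theta) = 1/sqrt(sin^2 theta + 1/g_cap^2)`` reflects that a flat ski
    distributes load over the base (stiff response at small depth) while an
    edged ski concentrates it on the edge, which then penetrates deeper; it
    is smooth and capped at ``g_cap``.  Shipped values are plausible for
    groomed race snow, not bench-calibrated; all are configurable.
    """

    k_p: float = 3.0e4    # N/m^2 penetration stiffness per edge length
    c_p: float = 0.2      # s/m penetration rate factor
    k_s: float = 4.0e5    # N/m^2 shear stiffness per edge length
    mu: float = 0.1       # Coulomb friction coefficient
    v_eps: float = 0.05   # m/s velocity regularization speed
    g_cap: float = 2.0    # cap of the edging-angle factor (flat-ski value)
    d_eps: float = 1e-3   # m smoothing of the depth ramp

    def validate(self) -> None:
        for name in ("k_p", "c_p", "k_s", "mu", "v_eps", "g_cap", "d_eps"):
            if getattr(self, name) < 0:
                raise ModelError(f"contact parameter {name} must be >= 0")

    def g_theta(self, theta):
        s = np.sin(theta)
        return 1.0 / np.sqrt(s * s + 1.0 / self.g_cap ** 2)


@dataclass
class ContactState:
    """Per-segment contact kinematics: depth, depth rate, edging angle,
    edge-point velocity (d <= 0 means no contact)."""

    depth: np.ndarray
    depth_rate: np.ndarray
    edging: np.ndarray
    edge_velocity: np.ndarray


def edging_angle(segment_rotation, snow: SnowPlane):
    """Angle between the ski base plane and the snow plane, in [0, pi/2].

    ``segment_rotation``: world-from-segment rotation matrices (..., 3, 3);
    the segment base normal is its +z axis.
    """
    R = np.asarray(segment_rotation)
    RtR = np.einsum("...ij,...kj->...ik", R, R)
    if not np.allclose(np.real(RtR), np.eye(3), atol=1e-6):
        raise ModelError("segment pose is not a valid rotation")
    base_n = R[..., :, 2]
    s = smooth_norm(cross(base_n, snow.normal), eps=0.0)
    c = np.abs(np.sum(base_n * snow.normal, axis=-1))
    return np.arctan2(np.real(s), np.real(c)) if not np.iscomplexobj(R) else np.arctan2(s, c)


def _edging_smooth(base_n, normal):
    """Complex-safe edging angle from the base normal (no validation)."""
    s2 = np.sum(cross(base_n, normal) ** 2, axis=-1)
    return np.arcsin(np.sqrt(s2 + 1e-14) / np.sqrt(np.sum(base_n * base_n, axis=-1)))


def penetration_force(d, ddot, theta, params: Optional[ContactParams] = None,
                      seg_length: float = 1.0):
    """Elastic penetration force magnitude (N, >= 0) along the snow normal.

    Fp = k_p * L * max(d, 0) * g(theta) * max(1 + c_p * ddot, 0); all maxima
    smoothed.  Zero for d <= 0; the rate factor never produces adhesion.
    """
    p = params or ContactParams()
    return (
        p.k_p * seg_length * smooth_max0(d, p.d_eps) * p.g_theta(theta)
        * smooth_max0(1.0 + p.c_p * ddot, 1e-3)
    )


def shear_force(d, params: Optional[ContactParams] = None, lateral_direction=(0, 1, 0),
                v_lat=0.0, seg_length: float = 1.0):
    """Shear force vector in the snow plane, opposing lateral slip.

    Magnitude k_s * L * max(d, 0) scaled by a smooth saturation of the
    lateral slip speed; direction along ``-sign(v_lat) * lateral_direction``.
    """
    p = params or ContactParams()
    lat = np.asarray(lateral_direction)
    mag = p.k_s * seg_length * smooth_max0(d, p.d_eps)
    return -(mag * smooth_sat(v_lat, p.v_eps))[..., None] * lat


def friction_force(normal_force, velocity, mu: float = 0.1, v_eps: float = 0.01):
    """Coulomb friction, velocity-regularized: -mu*N*v/sqrt(|v|^2+v_eps^2)."""
    v = np.asarray(velocity)
    speed = smooth_norm(v, eps=v_eps)
    return -(mu * np.asarray(normal_force) / speed)[..., None] * v


@dataclass
class SegmentPose:
    """Minimal kinematic state of one ski segment for contact evaluation."""

    R: np.ndarray          # (...,3,3) world-from-segment
    p: np.ndarray          # (...,3) segment origin, world
    v: np.ndarray          # (...,3) origin velocity, world
    omega: np.ndarray      # (...,3) angular velocity, world
    mid_local: np.ndarray  # (3,) segment midpoint in the segment frame
    seg_length: float
    half_width: float


def _edge_wrench(pose: SegmentPose, snow: SnowPlane, params: ContactParams, side: float,
                 about, theta):
    """Contact wrench contribution of one edge (about the point ``about``)."""
    e_loc = pose.mid_local + np.array([0.0, side * pose.half_width, 0.0])
    r_e = np.einsum("...ij,j->...i", pose.R, e_loc)
    p_e = pose.p + r_e
    v_e = pose.v + cross(pose.omega, r_e)
    n = snow.normal
    d = -np.sum((p_e - snow.point) * n, axis=-1)
    ddot = -np.sum(v_e * n, axis=-1)

    fp_mag = penetration_force(d, ddot, theta, params, pose.seg_length)
    f_p = fp_mag[..., None] * n

    # edge tangent: ski long axis projected into the snow plane
    x_w = pose.R[..., :, 0]
    t = x_w - np.sum(x_w * n, axis=-1)[..., None] * n
    t = t / smooth_norm(t, eps=1e-6)[..., None]
    lat = cross(np.broadcast_to(n, t.shape), t)
    v_lat = np.sum(v_e * lat, axis=-1)
    f_s = shear_force(d, params, lat, v_lat, pose.seg_length)

    v_plane = v_e - np.sum(v_e * n, axis=-1)[..., None] * n
    f_f = friction_force(fp_mag, v_plane, params.mu, params.v_eps)

    force = f_p + f_s + f_f
    torque = cross(p_e - about, force)
    state = ContactState(d, ddot, theta, v_e)
    return force, torque, state


def contact_wrench(pose: SegmentPose, snow: SnowPlane, params: Optional[ContactParams] = None,
                   about=None):
    """Total contact wrench on one ski segment (force, torque about COM).

    Sums the penetration, shear and friction contributions of both segment
    edges; airborne segments (both edges above the plane) give a zero wrench
    up to the smoothing floor.
    """
    params = params or ContactParams()
    params.validate()
    base_n = pose.R[..., :, 2]
    theta = _edging_smooth(base_n, snow.normal)
    if about is None:
        about = pose.p + np.einsum("...ij,j->...i", pose.R, pose.mid_local)
    f1, t1, s1 = _edge_wrench(pose, snow, params, +1.0, about, theta)
    f2, t2, s2 = _edge_wrench(pose, snow, params, -1.0, about, theta)
    return f1 + f2, t1 + t2, (s1, s2)


def ski_contact_loads(model: MultibodyModel, kin: Kinematics, snow: SnowPlane,
                      params: Optional[ContactParams] = None):
    """Contact wrenches for every ski segment of an assembled model.

    Returns (ext_force, ext_torque) arrays shaped (..., n_bodies, 3): world
    forces acting at each body origin plus accompanying torques, ready for
    :func:`skitrack.model_core.inverse_dynamics`.
    """
    params = params or ContactParams()
    batch = kin.p.shape[:-2]
    dt = kin.p.dtype
    F = np.zeros(batch + (model.n_bodies, 3), dtype=dt)
    N = np.zeros_like(F)
    for b, seg in enumerate(model.segments):
        if not seg.meta.get("ski_segment"):
            continue
        pose = SegmentPose(
            kin.R[..., b, :, :], kin.p[..., b, :], kin.v[..., b, :],
            kin.omega[..., b, :], np.asarray(seg.com, float),
            seg.meta["seg_length"], seg.meta["half_width"],
        )
        f, t, _ = contact_wrench(pose, snow, params, about=kin.p[..., b, :])
        F[..., b, :] += f
        N[..., b, :] += t
    return F, N
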
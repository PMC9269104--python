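"""Post-processing of tracking solutions: tracking errors, turn geometry,
net joint moments, and intersegmental knee loads.

Conventions follow standard biomechanical reporting: joint moments are
internal moments with hip flexion/adduction/internal rotation, knee
extension, ankle dorsiflexion and lumbar extension/lateral bending/left
rotation positive; intersegmental knee loads are expressed in the shank
frame (x anterior-posterior, y superior-inferior, z medial-lateral) with
positive moments meaning internal knee extension, adduction and internal
rotation.  Left-side frontal/transverse axes are mirrored so that mirrored
motions yield identical adduction/rotation values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model_core as mc
from .model_core import ModelError
from .rotations import cross
from .ski_snow import SnowPlane, ski_contact_loads
from .system import SkiSystem
from .tracking import Solution

__all__ = [
    "ShankFrame",
    "JointMomentSeries",
    "rmsd",
    "project_to_plane",
    "turn_radius",
    "steering_phase",
    "net_joint_moments",
    "intersegmental_knee_loads",
    "grf_distribution",
    "speed_series",
]


# --------------------------------------------------------------------------
# scalar metrics
# --------------------------------------------------------------------------

def rmsd(series_a, series_b):
    """Root mean squared difference between two equal-length series."""
    a, b = np.asarray(series_a, float), np.asarray(series_b, float)
    if a.shape != b.shape or a.size < 1:
        raise ModelError(f"rmsd: shapes {a.shape} and {b.shape} do not match")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# --------------------------------------------------------------------------
# turn geometry
# --------------------------------------------------------------------------

def project_to_plane(points, snow: SnowPlane):
    """In-plane 2D coordinates of world points (basis: fall line, contour)."""
    n = snow.normal
    up = np.array([0.0, 0.0, 1.0])
    e1 = up - np.dot(up, n) * n           # uphill direction in the plane
    if np.linalg.norm(e1) < 1e-12:        # horizontal plane: use x
        e1 = np.array([1.0, 0.0, 0.0])
    e1 = -e1 / np.linalg.norm(e1)         # fall line (downhill)
    e2 = np.cross(n, e1)
    rel = np.asarray(points, float) - snow.point
    return np.stack([rel @ e1, rel @ e2], axis=-1)


def _circumradius(pts):
    """Algebraic (Kasa) circle fit radius of 2D points; inf if colinear."""
    c = pts - pts.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[0] < 1e-12 or sv[-1] / sv[0] < 1e-9:  # numerically colinear window
        return np.inf
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return np.inf
    r2 = sol[2] + sol[0] ** 2 + sol[1] ** 2
    if not np.isfinite(r2) or r2 <= 0:
        return np.inf
    return float(np.sqrt(r2))


def turn_radius(track_points, window: int = 25, cap: float = 1000.0):
    """Turn radius over a sliding window of in-plane track points.

    ``track_points``: (N, 2) points already projected onto the snow plane
    (see :func:`project_to_plane`); ``window``: odd number of samples
    (default 25 = 0.5 s at 50 Hz).  Near-straight windows are capped at
    ``cap`` meters and flagged.

    Returns ``(radius, straight_flag)`` arrays of length N.
    """
    pts = np.asarray(track_points, float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ModelError("turn_radius needs >= 3 projected 2D points")
    window = max(3, int(window))
    N = pts.shape[0]
    radius = np.empty(N)
    straight = np.zeros(N, bool)
    half = window // 2
    for i in range(N):
        lo, hi = max(0, i - half), min(N, i + half + 1)
        r = _circumradius(pts[lo:hi])
        if not np.isfinite(r) or r > cap:
            radius[i] = cap
            straight[i] = True
        else:
            radius[i] = r
    return radius, straight


def steering_phase(radius_series, sidecut_radius: float = 32.0):
    """First/last sample indices with turn radius below the sidecut radius.

    Returns ``(first, last)`` (inclusive) or ``None`` when the radius never
    drops below the sidecut radius.
    """
    below = np.nonzero(np.asarray(radius_series, float) < sidecut_radius)[0]
    if below.size == 0:
        return None
    return int(below[0]), int(below[-1])


# --------------------------------------------------------------------------
# joint moments
# --------------------------------------------------------------------------

@dataclass
class JointMomentSeries:
    """Net joint moments per skier coordinate (normalized, N*m/kg).

    ``moments`` maps coordinate name -> (N,) series of muscle-generated net
    moments; ``boot`` holds the passive ski-boot ankle moments separately;
    ``raw`` is in N*m.
    """

    moments: dict
    boot: dict
    body_mass: float
    raw: dict = field(default_factory=dict)


def _state_derivatives(sol: Solution, sysm: SkiSystem):
    """Implicit-Euler consistent state derivatives on the node grid.

    The collocation constraints cover intervals 1..N-1, so the muscle
    states at node 0 are algebraically free; they are replaced by the
    node-1 values before computing muscle-derived quantities.
    """
    h = float(sol.times[1] - sol.times[0])
    X = np.array(sol.states, float)
    if X.shape[0] > 1 and sysm.n_mus:
        X[0, 2 * sysm.n_q:] = X[1, 2 * sysm.n_q:]
    Xd = np.vstack([(X[1] - X[0]) / h, np.diff(X, axis=0) / h])
    return sysm.unpack(X), sysm.unpack(Xd)


def net_joint_moments(solution: Solution, system: SkiSystem | None = None) -> JointMomentSeries:
    """Muscle-generated net moments at the skier joints, plus boot moments.

    Moments are additive over muscles (tau = R^T F) and normalized by the
    skier's body mass (ski segments excluded).  The passive boot moment at
    each ankle is reported separately, matching the convention of keeping
    boot-induced ankle moments out of the muscular net moment.
    """
    sysm = system or solution.problem.system
    st, std = _state_derivatives(solution, sysm)
    geo = sysm.muscles.musculotendon_geometry(st.q)
    _, f_t = sysm.muscles.contraction_residual(st.s, std.s, st.a, geo.l_mt)
    tau = sysm.muscles.muscle_joint_moments(st.q, np.real(f_t), geo)
    body_mass = sum(
        s.mass for s in sysm.model.segments if not s.meta.get("ski_segment")
    )
    moments, raw = {}, {}
    for name in sysm.model.coord_names:
        if name.startswith(("ski_", "l_ski", "r_ski")) or "_bend" in name:
            continue
        k = sysm.model.coord_index(name)
        raw[name] = np.real(tau[..., k])
        moments[name] = raw[name] / body_mass
    boot = {
        name: np.real(val) / body_mass
        for name, val in sysm.boot_moment_series(st.q, st.qdot).items()
    }
    return JointMomentSeries(moments, boot, body_mass, raw)


# --------------------------------------------------------------------------
# intersegmental knee loads
# --------------------------------------------------------------------------

@dataclass
class ShankFrame:
    """Right-handed orthonormal shank frame at the knee center.

    Axes (world columns): x anterior-posterior, y superior-inferior,
    z medial-lateral; the moment axes are mirrored per side so positive
    components mean internal knee extension, adduction, internal rotation.
    """

    origin: np.ndarray   # (N, 3) knee center, world
    axes: np.ndarray     # (N, 3, 3) columns = x, y, z


def intersegmental_knee_loads(solution: Solution, system: SkiSystem | None = None,
                              side: str = "r") -> dict:
    """6-DOF intersegmental knee force/moment series in the shank frame.

    Newton-Euler balances are solved segment by segment from the outermost
    ski segments through the foot to the shank; each step balances segment
    inertia, gravity and contact forces against the joint load passed
    inboard.  The load returned is the wrench the thigh exerts on the shank
    across the knee, resolved in the shank frame.

    Returns ``{'force': (N,3), 'moment': (N,3), 'frame': ShankFrame,
    'force_per_kg': ..., 'moment_per_kg': ...}`` with component order
    (anterior, superior, medial) for forces and (adduction, internal
    rotation, extension) for moments, positive as internal moments.
    """
    if side not in ("l", "r"):
        raise ModelError(f"side must be 'l' or 'r', got {side!r}")
    sysm = system or solution.problem.system
    model = sysm.model
    st, std = _state_derivatives(solution, sysm)
    kin = mc.body_kinematics(model, st.q, st.qdot, std.qdot)
    if sysm.snow is not None:
        ext_f, ext_n = ski_contact_loads(model, kin, sysm.snow, sysm.contact)
        ext_f, ext_n = np.real(ext_f), np.real(ext_n)
    else:
        ext_f = ext_n = np.zeros(kin.p.shape)

    shank = model.body_index(f"shank_{side}")
    # distal chain: every body whose ancestry passes through the shank
    chain = []
    for b in range(model.n_bodies):
        a = b
        while a >= 0:
            if a == shank:
                chain.append(b)
                break
            a = model.joints[a].parent
    children = {b: [c for c in chain if model.joints[c].parent == b] for b in chain}

    g = model.gravity
    masses = np.array([s.mass for s in model.segments])
    Ib = np.stack([np.asarray(s.inertia, float) for s in model.segments])
    Iw = np.einsum("...bij,bjk,...blk->...bil", kin.R, Ib, kin.R)
    Fnet = masses[:, None] * (kin.acom - g)
    Nnet = np.einsum("...bij,...bj->...bi", Iw, kin.omegadot) + cross(
        kin.omega, np.einsum("...bij,...bj->...bi", Iw, kin.omega)
    )

    def recurse(b):
        """Wrench (force, moment about body b's inboard joint) the parent
        must transmit to body b's subtree."""
        f = Fnet[..., b, :] - ext_f[..., b, :]
        n = (
            Nnet[..., b, :]
            + cross(kin.com[..., b, :] - kin.p[..., b, :], Fnet[..., b, :])
            - ext_n[..., b, :]
        )
        for c in children[b]:
            fc, nc = recurse(c)
            f = f + fc
            n = n + nc + cross(kin.p[..., c, :] - kin.p[..., b, :], fc)
        return f, n

    f_knee, n_knee = recurse(shank)  # about the shank origin = knee center
    f_knee, n_knee = np.real(f_knee), np.real(n_knee)

    R = np.real(kin.R[..., shank, :, :])
    e_ant = R[..., :, 0]
    e_sup = R[..., :, 2]
    e_left = R[..., :, 1]
    sgn = 1.0 if side == "r" else -1.0
    # force components: anterior, superior, medial(+)
    medial = sgn * e_left
    F = np.stack(
        [np.sum(f_knee * e_ant, -1), np.sum(f_knee * e_sup, -1),
         np.sum(f_knee * medial, -1)], axis=-1
    )
    # moment components: adduction(+), internal rotation(+), extension(+)
    M = np.stack(
        [sgn * np.sum(n_knee * e_ant, -1), sgn * np.sum(n_knee * e_sup, -1),
         np.sum(n_knee * (-e_left), -1)], axis=-1
    )
    body_mass = sum(s.mass for s in model.segments if not s.meta.get("ski_segment"))
    frame = ShankFrame(np.real(kin.p[..., shank, :]),
                       np.stack([e_ant, e_sup, medial], axis=-1))
    denom = body_mass if body_mass > 0 else np.nan
    return {
        "force": F, "moment": M, "frame": frame,
        "force_per_kg": F / denom, "moment_per_kg": M / denom,
    }


# --------------------------------------------------------------------------
# GRF distribution and speed
# --------------------------------------------------------------------------

def grf_distribution(grf_outside, grf_inside, phase=None):
    """Mean outside-leg share of the total ground reaction force.

    ``phase``: optional (first, last) sample indices (e.g. the steering
    phase) over which to average.
    """
    out = np.abs(np.asarray(grf_outside, float))
    ins = np.abs(np.asarray(grf_inside, float))
    if out.shape != ins.shape:
        raise ModelError("GRF series lengths do not match")
    if phase is not None:
        i0, i1 = phase
        out, ins = out[i0:i1 + 1], ins[i0:i1 + 1]
    total = out + ins
    if np.all(total <= 0):
        raise ModelError("total GRF is zero over the evaluated phase")
    good = total > 0
    return float(np.mean(out[good] / total[good]))


def hip_midpoint(solution: Solution, system: SkiSystem | None = None):
    """World trajectory of the midpoint between the hip joint centers."""
    sysm = system or solution.problem.system
    st = sysm.unpack(solution.states)
    kin = mc.body_kinematics(sysm.model, st.q)
    hips = []
    for side in ("r", "l"):
        hips.append(np.real(kin.p[..., sysm.model.body_index(f"thigh_{side}"), :]))
    return 0.5 * (hips[0] + hips[1])


def speed_series(solution: Solution, system: SkiSystem | None = None,
                 smooth_window: int = 5):
    """Speed of the hip-joint midpoint (m/s), central-differenced.

    Positions are lightly smoothed with a centered moving average of
    ``smooth_window`` samples before differentiation.
    """
    mid = hip_midpoint(solution, system)
    t = solution.times
    if smooth_window > 1:
        k = int(smooth_window) | 1
        pad = k // 2
        # odd reflection preserves linear trends at the boundaries
        padded = np.pad(mid, ((pad, pad), (0, 0)), mode="reflect", reflect_type="odd")
        kernel = np.ones(k) / k
        mid = np.stack([np.convolve(padded[:, i], kernel, "valid") for i in range(3)], -1)
    vel = np.gradient(mid, t, axis=0)
    return np.linalg.norm(vel, axis=-1)
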
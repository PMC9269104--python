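"""Batched rotation utilities.

All functions broadcast over arbitrary leading batch axes and preserve the
input dtype (complex inputs stay complex, for complex-step differentiation).
Rotation matrices map body-frame vectors to the world/parent frame:
``v_world = R @ v_body``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["axis_angle", "euler_axes_rotation", "cross", "rotation_angle_between_planes"]


def cross(a, b):
    """Batched cross product over the last axis (complex-safe)."""
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return np.stack(
        [ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1
    )


def axis_angle(axis, angle):
    """Rodrigues rotation matrix about a fixed unit ``axis`` by ``angle``.

    ``axis``: shape (3,) constant; ``angle``: any batch shape.  Returns
    (..., 3, 3).
    """
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle)
    c = np.cos(angle)
    s = np.sin(angle)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    eye = np.eye(3)
    # R = I + sin K + (1-cos) K^2, broadcast over batch axes of angle
    K2 = K @ K
    return (
        eye
        + s[..., None, None] * K
        + (1.0 - c)[..., None, None] * K2
    )


def euler_axes_rotation(axes, q):
    """Composition R = R(a1,q1) @ R(a2,q2) @ ... for a list of fixed axes.

    ``axes``: (n, 3) unit axes; ``q``: (..., n).  Returns (..., 3, 3).
    Each successive rotation is intrinsic (applied in the already-rotated
    frame), which is what the chained matrix product expresses.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    R = axis_angle(axes[0], q[..., 0])
    for j in range(1, axes.shape[0]):
        R = R @ axis_angle(axes[j], q[..., j])
    return R


def rotation_angle_between_planes(n1, n2):
    """Angle in [0, pi/2] between two planes given unit normals (batched)."""
    s = np.linalg.norm(np.cross(n1, n2), axis=-1)
    c = np.abs(np.sum(n1 * n2, axis=-1))
    return np.arctan2(s, c)
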
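"""Quaternion and rotation-matrix utilities.

Conventions
-----------
Quaternions are scalar-first ``(w, x, y, z)`` and use the Hamilton product.
A rotation written ``b_R_a`` (or quaternion ``q`` "of frame a in frame b")
maps coordinates expressed in frame *a* to coordinates expressed in frame
*b*:  ``v_b = b_R_a @ v_a``.  Composition therefore reads right-to-left,
matching the segment-orientation chain ``g_R_seg = g_R_s @ s_R_seg``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_to_matrix",
    "quat_from_matrix",
    "quat_angle_deg",
    "rotation_angle_deg",
    "axis_angle_matrix",
    "twist_angle",
    "random_rotation",
    "is_rotation_matrix",
]


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q / |q|``; works on a single quaternion or an (N, 4) array."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2 (broadcasts over leading axes)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (v_out = R(q) v)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    out = quat_multiply(quat_multiply(q, qv), quat_conjugate(q))
    return out[..., 1:]


def quat_from_axis_angle(axis: np.ndarray, angle) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` rad about ``axis``.

    ``angle`` may be an array; the result then has shape (N, 4).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    w = np.cos(half)
    s = np.sin(half)
    return np.stack(
        [w, s * axis[0], s * axis[1], s * axis[2]], axis=-1
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix/matrices from scalar-first quaternion(s)."""
    q = np.asarray(q, dtype=float)
    # scipy uses scalar-last ordering
    return _ScipyRotation.from_quat(np.roll(q, -1, axis=-1)).as_matrix()


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Scalar-first quaternion(s) from rotation matrix/matrices (w >= 0)."""
    q = _ScipyRotation.from_matrix(np.asarray(R, dtype=float)).as_quat()
    q = np.roll(q, 1, axis=-1)
    # fix the double-cover sign for reproducibility
    flip = q[..., 0] < 0
    q = np.where(flip[..., None], -q, q)
    return q


def quat_angle_deg(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic angle (degrees) between two orientations."""
    d = quat_multiply(quat_conjugate(q1), q2)
    w = np.clip(np.abs(d[..., 0]), -1.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def rotation_angle_deg(R1: np.ndarray, R2: np.ndarray | None = None) -> float:
    """Angle of ``R1`` (or of ``R1 @ R2.T`` when ``R2`` is given), degrees."""
    R = np.asarray(R1, dtype=float)
    if R2 is not None:
        R = R @ np.asarray(R2, dtype=float).T
    c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return quat_to_matrix(quat_from_axis_angle(axis, angle_rad))


def twist_angle(q_rel: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Twist component (rad, in (-pi, pi]) of ``q_rel`` about unit ``axis``.

    Decomposes the relative rotation as swing ∘ twist with the twist about
    ``axis``; used for pronation/supination, where the axis is the distal
    segment's longitudinal direction.
    """
    q = np.asarray(q_rel, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    w = q[..., 0]
    proj = q[..., 1:] @ axis
    ang = 2.0 * np.arctan2(proj, w)
    # map to (-pi, pi]
    return (ang + np.pi) % (2.0 * np.pi) - np.pi


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed random rotation matrix."""
    return _ScipyRotation.random(random_state=rng).as_matrix()


def is_rotation_matrix(R: np.ndarray, tol: float = 1e-8) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )
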
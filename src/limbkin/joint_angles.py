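"""Joint-angle extraction from segment orientation traces.

Flexion/abduction-type angles are computed by projecting the distal
segment's longitudinal axis (expressed in the proximal segment's frame)
onto the joint's anatomical plane and taking the signed four-quadrant
angle against the proximal longitudinal axis:

    v_p   = v - (v . n / |n|^2) n
    theta = atan2(|v1 x v2|, v1 . v2),  sign from (v1 x v2) . sign_axis

The flexion/extension plane of the elbow, wrist and fingers is normal to
the proximal segment's medio-lateral (y) axis, which excludes ulnar/radial
deviation.  Shoulder flexion uses the sternum's sagittal plane (normal y)
and shoulder abduction the frontal plane (normal z, the anterior axis).
Forearm pronation/supination has no plane-projection form: it is computed
as the twist component of the forearm-relative-to-upper-arm rotation about
the forearm's longitudinal axis (swing-twist decomposition).

Samples where the projected vector nearly vanishes (the segment axis close
to the plane normal — e.g. the abduction angle of an arm flexed to 90°)
are marked missing (NaN) and the run continues; the conditioning threshold
is one degree of residual projection by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np

from .datamodel import JointAngleTrace, OrientationTrace
from .errors import ProjectionDegenerateError
from .rotations import quat_conjugate, quat_multiply, quat_to_matrix, twist_angle

logger = logging.getLogger(__name__)

_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}

#: hard degeneracy threshold for a single projection
PROJECTION_EPS = 1e-6
#: default conditioning guard in compute_joint_angles (degrees)
DEFAULT_CONDITIONING_DEG = 1.0


def project_vector(v: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Project ``v`` onto the plane with normal ``n``."""
    v = np.asarray(v, dtype=float)
    n = np.asarray(n, dtype=float)
    nn = float(np.dot(n, n))
    if nn == 0.0:
        raise ValueError("plane normal must be nonzero")
    p = v - (np.dot(v, n) / nn) * n
    if np.linalg.norm(p) < PROJECTION_EPS * np.linalg.norm(v):
        raise ProjectionDegenerateError(
            "vector normal to projection plane; angle undefined"
        )
    return p


def angle_between(
    v1: np.ndarray, v2: np.ndarray, sign_axis: Optional[np.ndarray] = None
) -> float:
    """Four-quadrant angle between two vectors, degrees.

    Unsigned result in [0, 180]; with ``sign_axis`` the angle is negated
    when ``(v1 x v2) . sign_axis < 0``, extending the range to
    [-180, 180].
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if np.linalg.norm(v1) == 0.0 or np.linalg.norm(v2) == 0.0:
        raise ValueError("angle undefined for zero vectors")
    c = np.cross(v1, v2)
    theta = math.degrees(math.atan2(float(np.linalg.norm(c)), float(np.dot(v1, v2))))
    if sign_axis is not None and float(np.dot(c, np.asarray(sign_axis, float))) < 0.0:
        theta = -theta
    return theta


@dataclass(frozen=True)
class JointDefinition:
    """How one joint channel is computed.

    ``kind='projection'``: the distal longitudinal (x) axis, expressed in
    the proximal frame, is projected onto the plane normal to the proximal
    ``plane_normal`` axis and measured against the proximal ``reference``
    axis; ``sign_axis`` (collinear with the normal, sign encoding the
    positive rotation direction) fixes the sign so flexion/abduction are
    positive.

    ``kind='twist'``: the twist of the proximal-to-distal relative rotation
    about the distal longitudinal axis, multiplied by ``twist_sign``.
    """

    name: str
    proximal: str
    distal: str
    kind: str = "projection"
    plane_normal: str = "y"
    reference: str = "x"
    sign_axis: str = "y"
    twist_sign: int = 1


def default_joint_definitions(side: str = "right") -> List[JointDefinition]:
    """The paper-protocol joint set with side-resolved sign conventions.

    In a right-arm frame (x up at neutral, y lateral/right, z anterior)
    flexion of hanging segments is a rotation about +y and abduction about
    -z; laterality flips the abduction and supination signs for the left
    arm.
    """
    abd_sign = "-z" if side == "right" else "z"
    sup_sign = -1 if side == "right" else 1
    defs = [
        JointDefinition("shoulder_flexion", "sternum", "upper_arm",
                        plane_normal="y", sign_axis="y"),
        JointDefinition("shoulder_abduction", "sternum", "upper_arm",
                        plane_normal="z", sign_axis=abd_sign),
        JointDefinition("elbow_flexion", "upper_arm", "forearm",
                        plane_normal="y", sign_axis="y"),
        JointDefinition("forearm_supination", "upper_arm", "forearm",
                        kind="twist", twist_sign=sup_sign),
        JointDefinition("wrist_flexion", "forearm", "hand",
                        plane_normal="y", sign_axis="y"),
        JointDefinition("thumb_flexion", "hand", "thumb",
                        plane_normal="y", sign_axis="y"),
        JointDefinition("index_flexion", "hand", "index",
                        plane_normal="y", sign_axis="y"),
        JointDefinition("middle_flexion", "hand", "middle",
                        plane_normal="y", sign_axis="y"),
    ]
    return defs


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def _projection_angles(
    q_prox: np.ndarray,
    q_dist: np.ndarray,
    jd: JointDefinition,
    conditioning_deg: float,
) -> np.ndarray:
    # distal longitudinal axis expressed in the proximal frame:
    # v = R_prox^T R_dist x_hat, per sample
    R_prox = quat_to_matrix(q_prox)
    R_dist = quat_to_matrix(q_dist)
    u = R_dist[:, :, 0]  # distal x in global
    v = np.einsum("nij,nj->ni", np.swapaxes(R_prox, 1, 2), u)

    n = _AXIS_VECTORS[jd.plane_normal]
    ref = _AXIS_VECTORS[jd.reference]
    s = _AXIS_VECTORS[jd.sign_axis]

    p = v - np.outer(v @ n, n)
    pnorm = np.linalg.norm(p, axis=1)
    valid = pnorm >= math.sin(math.radians(conditioning_deg)) * np.linalg.norm(
        v, axis=1
    )

    c = np.cross(np.broadcast_to(ref, p.shape), p)
    theta = np.degrees(np.arctan2(np.linalg.norm(c, axis=1), p @ ref))
    theta = np.where(c @ s < 0.0, -theta, theta)
    theta = np.where(valid, theta, np.nan)
    n_missing = int((~valid).sum())
    if n_missing:
        logger.info(
            "%s: %d/%d sample(s) degenerate (axis near the projection "
            "normal), marked missing", jd.name, n_missing, valid.size,
        )
    return theta


def _twist_angles(q_prox: np.ndarray, q_dist: np.ndarray, jd: JointDefinition) -> np.ndarray:
    q_rel = quat_multiply(quat_conjugate(q_prox), q_dist)
    ang = twist_angle(q_rel, _AXIS_VECTORS["x"])
    return jd.twist_sign * np.degrees(ang)


def compute_joint_angles(
    segments: Mapping[str, OrientationTrace],
    definitions: Optional[List[JointDefinition]] = None,
    neutral_reference: Optional[Mapping[str, float]] = None,
    side: str = "right",
    conditioning_deg: float = DEFAULT_CONDITIONING_DEG,
) -> JointAngleTrace:
    """Compute all joint channels from segment orientation traces.

    ``segments`` maps segment labels to ``segment_in_global`` orientation
    traces on a common timebase.  ``neutral_reference`` holds per-channel
    neutral-pose angles (degrees) to subtract so the neutral pose reads
    zero; with calibrated frames these are zero by construction, so the
    default is no offset.
    """
    definitions = definitions or default_joint_definitions(side)
    neutral_reference = neutral_reference or {}
    time = None
    out: Dict[str, np.ndarray] = {}
    for jd in definitions:
        if jd.proximal not in segments or jd.distal not in segments:
            continue
        prox = segments[jd.proximal]
        dist = segments[jd.distal]
        for trace in (prox, dist):
            if trace.frame != "segment_in_global":
                raise ValueError(
                    f"{jd.name}: traces must be segment_in_global, got {trace.frame!r}"
                )
        if time is None:
            time = prox.time
        if prox.n_samples != dist.n_samples:
            raise ValueError(f"{jd.name}: proximal/distal traces not time-aligned")
        if jd.kind == "projection":
            theta = _projection_angles(prox.quat, dist.quat, jd, conditioning_deg)
        elif jd.kind == "twist":
            theta = _twist_angles(prox.quat, dist.quat, jd)
        else:
            raise ValueError(f"unknown joint kind {jd.kind!r}")
        theta = _wrap_deg(theta - neutral_reference.get(jd.name, 0.0))
        out[jd.name] = theta
    if time is None:
        raise ValueError("no joint definition matched the provided segments")
    return JointAngleTrace(time, out)
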
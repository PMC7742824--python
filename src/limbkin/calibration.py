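"""Sensor-to-segment calibration and global-frame definition.

Each anatomical axis is estimated as the normalized component-wise median
of either the accelerometer during a defined static posture (the gravity
vector seen in the sensor frame) or the gyroscope during a defined dynamic
movement (the rotation axis seen in the sensor frame).  For every sensor
two axes are measured, the third is their cross product, and one of the
measured axes is redefined to make the triad exactly orthonormal.  The
resulting matrix ``s_R_seg = [x_seg  y_seg  z_seg]`` holds the anatomical
axes as columns, expressed in the sensor frame.

Which posture/movement defines which axis of which segment is not
hard-coded: it is a declarative :class:`CalibrationProtocol`, shipped with
a default consistent with the sensing chain (the neutral pose defines the
longitudinal x-axes through gravity; arm/finger flexion movements define
the medio-lateral y-axes through their rotation axes; the neutral pose and
hip flexion define the global frame).

The left-arm protocol mirrors the right-arm one across the sagittal plane:
segment frames keep x longitudinal (up at neutral) and z anterior, with y
lateral; the sign of the trunk's hip-flexion axis flips between sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import yaml

from .datamodel import (
    HIP_FLEXION_ITEM,
    NEUTRAL_ITEM,
    GlobalFrameAlignment,
    LabelledRecordingSet,
    PLACEMENTS,
    RawImuRecording,
    SegmentCalibration,
    SensorPlacement,
)
from .errors import (
    CollinearAxesError,
    DegenerateAxisError,
    DegenerateHorizontalAxisError,
    IncompleteCalibrationSetError,
    NoMovementError,
)
from .orientation import correct_gyro_drift, detect_static_periods

DEFAULT_STILLNESS_THRESHOLD = math.radians(3.0)  # rad/s during static items
DEFAULT_MOVEMENT_THRESHOLD = math.radians(30.0)  # rad/s peak during dynamic items
DEFAULT_COLLINEARITY_LIMIT = 30.0  # deg; measured axes must be 30-150 deg apart

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class AxisEstimate:
    """A unit anatomical-axis direction measured in the sensor frame."""

    vector: np.ndarray
    source: str  # 'accelerometer_static' or 'gyroscope_dynamic'
    item_label: str = ""

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        n = np.linalg.norm(v)
        if not math.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise ValueError("axis estimate must be unit norm")
        object.__setattr__(self, "vector", v)


def estimate_axis_static(
    accel_window: np.ndarray,
    gyro_window: Optional[np.ndarray] = None,
    stillness_threshold: float = DEFAULT_STILLNESS_THRESHOLD,
    min_norm: float = 1.0,
    item_label: str = "",
) -> AxisEstimate:
    """Axis from a static posture: normalized component-wise median of the
    accelerometer window (v = median(a) / ||median(a)||).

    If the gyro window is supplied, stillness is checked against the
    3 deg/s threshold.  A median norm below ``min_norm`` (1 m/s^2) signals
    free fall or corrupt data and raises a degenerate-axis error.
    """
    accel = np.atleast_2d(np.asarray(accel_window, dtype=float))
    if gyro_window is not None:
        rates = np.linalg.norm(np.atleast_2d(gyro_window), axis=1)
        if rates.size and np.median(rates) >= stillness_threshold:
            raise DegenerateAxisError(
                "window is not static (median rate "
                f"{math.degrees(float(np.median(rates))):.1f} deg/s)"
            )
    med = np.median(accel, axis=0)
    norm = float(np.linalg.norm(med))
    if norm < min_norm:
        raise DegenerateAxisError(
            f"degenerate axis: median accel norm {norm:.3f} m/s^2 < {min_norm}"
        )
    return AxisEstimate(med / norm, "accelerometer_static", item_label)


def estimate_axis_dynamic(
    gyro_window: np.ndarray,
    movement_threshold: float = DEFAULT_MOVEMENT_THRESHOLD,
    item_label: str = "",
) -> AxisEstimate:
    """Axis from a dynamic movement: normalized component-wise median of
    the gyro samples in the moving portion of the window.

    Only samples whose rate norm exceeds half the window's peak norm enter
    the median, and each is sign-flipped into the hemisphere of the first
    such sample, so an oscillating movement (e.g. flex then return) yields
    the axis of its *initial* rotation direction.  Protocol items declare
    that movements begin in the anatomically positive direction.
    """
    gyro = np.atleast_2d(np.asarray(gyro_window, dtype=float))
    norms = np.linalg.norm(gyro, axis=1)
    peak = float(norms.max(initial=0.0))
    if peak <= movement_threshold:
        raise NoMovementError(
            f"no movement detected (peak rate {math.degrees(peak):.1f} deg/s "
            f"<= {math.degrees(movement_threshold):.0f} deg/s)"
        )
    sel = gyro[norms > 0.5 * peak]
    ref = sel[0]
    flipped = np.where((sel @ ref)[:, None] < 0.0, -sel, sel)
    med = np.median(flipped, axis=0)
    norm = float(np.linalg.norm(med))
    if norm == 0.0:
        raise NoMovementError("median rotation axis vanished")
    return AxisEstimate(med / norm, "gyroscope_dynamic", item_label)


def build_segment_frame(
    axis_a: AxisEstimate,
    axis_b: AxisEstimate,
    role_a: str,
    role_b: str,
    redefine: str = "b",
    placement: Optional[SensorPlacement] = None,
    collinearity_limit_deg: float = DEFAULT_COLLINEARITY_LIMIT,
) -> SegmentCalibration:
    """Build ``s_R_seg`` from two measured axes.

    ``role_a``/``role_b`` name the anatomical axes ('x', 'y' or 'z') the
    estimates correspond to; the third axis is their cross product and the
    axis flagged by ``redefine`` ('a' or 'b') is recomputed so the triad is
    exactly orthonormal and right-handed.
    """
    if role_a == role_b or role_a not in _AXES or role_b not in _AXES:
        raise ValueError(f"roles must be two distinct axes, got {role_a!r}, {role_b!r}")
    if redefine not in ("a", "b"):
        raise ValueError("redefine must be 'a' or 'b'")
    a, b = axis_a.vector, axis_b.vector
    ang = math.degrees(math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0))))
    if ang < collinearity_limit_deg or ang > 180.0 - collinearity_limit_deg:
        raise CollinearAxesError(ang)

    axes = {role_a: a, role_b: b}
    (role_c,) = set(_AXES) - {role_a, role_b}

    def _cross_for(target: str) -> np.ndarray:
        # ordered pair (p, q) with p x q = +target in a right-handed triad
        pair = {"z": ("x", "y"), "x": ("y", "z"), "y": ("z", "x")}[target]
        v = np.cross(axes[pair[0]], axes[pair[1]])
        return v / np.linalg.norm(v)

    axes[role_c] = _cross_for(role_c)
    redef_role = role_a if redefine == "a" else role_b
    axes[redef_role] = _cross_for(redef_role)

    R = np.column_stack([axes["x"], axes["y"], axes["z"]])
    placement = placement or SensorPlacement("sternum")
    provenance = {
        role_a: f"{axis_a.source}:{axis_a.item_label}",
        role_b: f"{axis_b.source}:{axis_b.item_label}",
        role_c: "cross_product",
        "redefined": redef_role,
    }
    return SegmentCalibration(placement, R, provenance)


@dataclass(frozen=True)
class AxisSpec:
    """One measured axis: which item defines which anatomical axis, how."""

    item: str
    axis: str  # 'x', 'y' or 'z'
    modality: str  # 'accel_static' or 'gyro_dynamic'
    sign: int = 1  # the measured direction equals sign * anatomical axis


@dataclass(frozen=True)
class SegmentPlan:
    primary: AxisSpec
    secondary: AxisSpec
    redefine: str = "secondary"  # which measured axis is recomputed


@dataclass
class CalibrationProtocol:
    """Declarative item -> axis mapping for the whole chain."""

    segments: Dict[str, SegmentPlan] = field(default_factory=dict)
    neutral_item: str = NEUTRAL_ITEM
    hip_item: str = HIP_FLEXION_ITEM
    side: str = "right"

    def required_items(self) -> list:
        items = {self.neutral_item, self.hip_item}
        for plan in self.segments.values():
            items.add(plan.primary.item)
            items.add(plan.secondary.item)
        return sorted(items)

    @classmethod
    def default(cls, side: str = "right") -> "CalibrationProtocol":
        """Default protocol for the 8-sensor chain.

        * x (longitudinal, up at neutral) of every segment from the
          neutral-pose gravity vector;
        * y (medio-lateral) of the trunk sensors from the hip-flexion
          rotation axis, of the arm sensors from a shoulder-flexion
          movement, and of the finger sensors from a finger-flexion
          movement (all beginning in the flexion direction);
        * z by cross product, y redefined for exact orthonormality.

        Trunk flexion rotates about the *negative* medio-lateral axis of a
        right-arm frame (y lateral = right), hence the side-dependent sign.
        """
        trunk_sign = -1 if side == "right" else 1
        limb_sign = 1

        def plan(dynamic_item: str, sign: int) -> SegmentPlan:
            return SegmentPlan(
                primary=AxisSpec(NEUTRAL_ITEM, "x", "accel_static", 1),
                secondary=AxisSpec(dynamic_item, "y", "gyro_dynamic", sign),
                redefine="secondary",
            )

        segments = {
            "sternum": plan(HIP_FLEXION_ITEM, trunk_sign),
            "shoulder": plan(HIP_FLEXION_ITEM, trunk_sign),
            "upper_arm": plan("arm_flexion", limb_sign),
            "forearm": plan("arm_flexion", limb_sign),
            "hand": plan("arm_flexion", limb_sign),
            "thumb": plan("finger_flexion", limb_sign),
            "index": plan("finger_flexion", limb_sign),
            "middle": plan("finger_flexion", limb_sign),
        }
        return cls(segments=segments, side=side)

    def to_yaml(self, path) -> None:
        payload = {
            "side": self.side,
            "neutral_item": self.neutral_item,
            "hip_item": self.hip_item,
            "segments": {
                seg: {
                    "primary": vars(plan.primary).copy(),
                    "secondary": vars(plan.secondary).copy(),
                    "redefine": plan.redefine,
                }
                for seg, plan in self.segments.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationProtocol":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        segments = {
            seg: SegmentPlan(
                primary=AxisSpec(**entry["primary"]),
                secondary=AxisSpec(**entry["secondary"]),
                redefine=entry.get("redefine", "secondary"),
            )
            for seg, entry in payload["segments"].items()
        }
        return cls(
            segments=segments,
            neutral_item=payload.get("neutral_item", NEUTRAL_ITEM),
            hip_item=payload.get("hip_item", HIP_FLEXION_ITEM),
            side=payload.get("side", "right"),
        )


def _corrected_gyro(rec: RawImuRecording) -> np.ndarray:
    """Drift-correct a dynamic item's gyro using its lead-in/out statics."""
    statics = detect_static_periods(rec.gyro, rec.fs)
    return correct_gyro_drift(rec.gyro, statics)


def _estimate_from_spec(
    spec: AxisSpec, rec: RawImuRecording
) -> AxisEstimate:
    if spec.modality == "accel_static":
        est = estimate_axis_static(rec.accel, rec.gyro, item_label=spec.item)
    elif spec.modality == "gyro_dynamic":
        est = estimate_axis_dynamic(_corrected_gyro(rec), item_label=spec.item)
    else:
        raise ValueError(f"unknown modality {spec.modality!r}")
    if spec.sign < 0:
        est = AxisEstimate(-est.vector, est.source, est.item_label)
    return est


def calibrate_all(
    recordings: LabelledRecordingSet,
    protocol: Optional[CalibrationProtocol] = None,
    side: str = "right",
) -> Dict[str, SegmentCalibration]:
    """Run the full sensor-to-segment calibration.

    Returns one :class:`SegmentCalibration` per placement present in the
    recording set.  Axis-estimation errors are re-raised annotated with the
    placement and item label.
    """
    protocol = protocol or CalibrationProtocol.default(side)
    recordings.require(protocol.required_items())
    out: Dict[str, SegmentCalibration] = {}
    for label in recordings.placements():
        if label not in protocol.segments:
            continue
        plan = protocol.segments[label]
        placement = SensorPlacement(label, side=protocol.side)
        estimates = []
        for spec in (plan.primary, plan.secondary):
            sensors = recordings[spec.item]
            if label not in sensors:
                raise IncompleteCalibrationSetError([f"{spec.item}/{label}"])
            try:
                estimates.append(_estimate_from_spec(spec, sensors[label]))
            except (DegenerateAxisError, NoMovementError) as exc:
                raise type(exc)(
                    f"{label} / {spec.item}: {exc}"
                ) from exc
        out[label] = build_segment_frame(
            estimates[0],
            estimates[1],
            plan.primary.axis,
            plan.secondary.axis,
            redefine="a" if plan.redefine == "primary" else "b",
            placement=placement,
        )
    return out


def define_global_frame(
    recordings: LabelledRecordingSet,
    protocol: Optional[CalibrationProtocol] = None,
    vertical_limit_deg: float = 15.0,
) -> GlobalFrameAlignment:
    """Define the shared global frame from the neutral pose and hip flexion.

    Per sensor: global z is the measured gravity (up) direction, global y
    is the hip-flexion rotation axis orthogonalized against z, global
    x = y × z.  The returned alignment maps each sensor's neutral-pose
    frame into this shared frame, with a diagnostic reporting how well the
    aligned gravity vectors agree across sensors.
    """
    protocol = protocol or CalibrationProtocol.default()
    recordings.require([protocol.neutral_item, protocol.hip_item])
    neutral = recordings[protocol.neutral_item]
    hip = recordings[protocol.hip_item]
    rotations: Dict[str, np.ndarray] = {}
    for label in sorted(neutral, key=PLACEMENTS.index):
        if label not in hip:
            raise IncompleteCalibrationSetError([f"{protocol.hip_item}/{label}"])
        z = estimate_axis_static(
            neutral[label].accel, neutral[label].gyro,
            item_label=protocol.neutral_item,
        ).vector
        h = estimate_axis_dynamic(
            _corrected_gyro(hip[label]), item_label=protocol.hip_item
        ).vector
        ang = math.degrees(math.acos(float(np.clip(abs(np.dot(h, z)), 0.0, 1.0))))
        if ang < vertical_limit_deg:
            raise DegenerateHorizontalAxisError(
                f"{label}: hip-flexion axis within {ang:.1f} deg of gravity"
            )
        y = h - np.dot(h, z) * z
        y /= np.linalg.norm(y)
        x = np.cross(y, z)
        # columns are the global axes in sensor coords -> transpose maps
        # sensor coords to global coords
        rotations[label] = np.column_stack([x, y, z]).T

    ups = []
    for label, g_R_s in rotations.items():
        grav = estimate_axis_static(
            neutral[label].accel, item_label=protocol.neutral_item
        ).vector
        ups.append(g_R_s @ grav)
    ups = np.asarray(ups)
    mean_up = ups.mean(axis=0)
    mean_up /= np.linalg.norm(mean_up)
    spread = math.degrees(
        max(math.acos(float(np.clip(np.dot(u, mean_up), -1.0, 1.0))) for u in ups)
    )
    return GlobalFrameAlignment(rotations, gravity_spread_deg=spread)
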
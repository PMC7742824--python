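"""End-to-end reconstruction: calibrate, estimate orientations, extract
joint angles and target-position features.

Each task recording is assumed to begin in (or near) the calibration
neutral posture: the initial orientation of every sensor is taken from the
global-frame alignment and re-anchored in inclination against the mean
accelerometer reading of the recording's initial static interval.  This
per-task reset bounds the integration drift each task can accumulate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationProtocol,
    calibrate_all,
    define_global_frame,
)
from .datamodel import (
    GlobalFrameAlignment,
    JointAngleTrace,
    LabelledRecordingSet,
    OrientationTrace,
    RawImuRecording,
    SegmentCalibration,
    SensorPlacement,
)
from .features_stats import TargetWindow, detect_target_window, extract_features
from .joint_angles import compute_joint_angles, default_joint_definitions
from .orientation import (
    DEFAULT_BETA,
    correct_gyro_drift,
    detect_static_periods,
    estimate_orientation,
    segment_orientation,
)
from .rotations import (
    quat_from_axis_angle,
    quat_from_matrix,
    quat_multiply,
    quat_normalize,
    quat_rotate,
)

logger = logging.getLogger(__name__)


def _initial_quaternion(
    g_R_s0: np.ndarray,
    rec: RawImuRecording,
    statics: List[Tuple[int, int]],
) -> np.ndarray:
    """Initial sensor orientation: the global alignment, tilt-corrected so
    the predicted gravity matches the accelerometer mean over the
    recording's initial static interval (heading kept from the alignment)."""
    q0 = quat_from_matrix(g_R_s0)
    if not statics or statics[0][0] > 0:
        return q0
    s, e = statics[0]
    a = rec.accel[s:e].mean(axis=0)
    norm = np.linalg.norm(a)
    if norm == 0.0:
        return q0
    up_meas = quat_rotate(q0, a / norm)  # measured gravity in global coords
    up = np.array([0.0, 0.0, 1.0])
    c = np.cross(up_meas, up)
    s_norm = np.linalg.norm(c)
    if s_norm < 1e-12:
        return q0
    angle = math.atan2(s_norm, float(np.dot(up_meas, up)))
    q_corr = quat_from_axis_angle(c / s_norm, angle)
    return quat_normalize(quat_multiply(q_corr, q0))


def reconstruct_segments(
    recordings: LabelledRecordingSet,
    task: str,
    calibrations: Mapping[str, SegmentCalibration],
    alignment: GlobalFrameAlignment,
    beta: float = DEFAULT_BETA,
) -> Dict[str, OrientationTrace]:
    """Drift-correct, fuse and calibrate every sensor of one task item.

    Returns segment-in-global orientation traces keyed by placement label.
    """
    out: Dict[str, OrientationTrace] = {}
    for label, rec in recordings[task].items():
        if label not in calibrations or label not in alignment.rotations:
            continue
        statics = detect_static_periods(rec.gyro, rec.fs)
        gyro = correct_gyro_drift(rec.gyro, statics)
        q0 = _initial_quaternion(alignment[label], rec, statics)
        sensor_trace = estimate_orientation(rec, q0, beta=beta, gyro_override=gyro)
        out[label] = segment_orientation(sensor_trace, calibrations[label])
    return out


def neutral_angle_reference(
    calibrations: Mapping[str, SegmentCalibration],
    alignment: GlobalFrameAlignment,
    side: str = "right",
) -> Dict[str, float]:
    """Joint angles implied by the calibration at the neutral pose.

    Subtracting these zeroes the channels at the neutral posture even when
    the estimated frames carry small calibration offsets.
    """
    segments: Dict[str, OrientationTrace] = {}
    t = np.array([0.0])
    for label, calib in calibrations.items():
        if label not in alignment.rotations:
            continue
        q = quat_normalize(
            quat_multiply(
                quat_from_matrix(alignment[label]),
                quat_from_matrix(calib.s_R_seg),
            )
        )
        segments[label] = OrientationTrace(
            SensorPlacement(label, side=calib.placement.side),
            t,
            q[None, :],
            "segment_in_global",
        )
    trace = compute_joint_angles(segments, side=side)
    return {
        name: float(vals[0])
        for name, vals in trace.angles.items()
        if np.isfinite(vals[0])
    }


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one task repetition."""

    task: str
    segments: Dict[str, OrientationTrace]
    angles: JointAngleTrace
    window: Optional[TargetWindow] = None
    features: Dict[str, float] = field(default_factory=dict)


def run_pipeline(
    recordings: LabelledRecordingSet,
    task: str,
    protocol: Optional[CalibrationProtocol] = None,
    side: str = "right",
    beta: float = DEFAULT_BETA,
    task_number: Optional[int] = None,
    window: Optional[TargetWindow] = None,
    window_channel: Optional[str] = None,
) -> PipelineResult:
    """Full reconstruction of one task item from a labelled recording set.

    Calibrates from the set's calibration items, reconstructs segment
    orientations, extracts joint angles (zero-referenced to the neutral
    pose) and, when a task number or explicit window/channel is given,
    target-position features.
    """
    protocol = protocol or CalibrationProtocol.default(side)
    calibrations = calibrate_all(recordings, protocol, side)
    alignment = define_global_frame(recordings, protocol)
    segments = reconstruct_segments(recordings, task, calibrations, alignment, beta)
    reference = neutral_angle_reference(calibrations, alignment, side)
    angles = compute_joint_angles(segments, neutral_reference=reference, side=side)

    features: Dict[str, float] = {}
    if window is None and (task_number is not None or window_channel is not None):
        window = detect_target_window(
            angles, task_number if task_number is not None else 0,
            channel=window_channel,
        )
    if window is not None:
        features = extract_features(angles, window)
    return PipelineResult(task, segments, angles, window, features)


#: the rigid-model movements: channel moved, amplitude (deg)
VALIDITY_MOVEMENTS: List[Tuple[str, float]] = [
    ("shoulder_flexion", 90.0),
    ("shoulder_abduction", 90.0),
    ("elbow_flexion", 90.0),
    ("wrist_flexion", 90.0),
    ("wrist_extension", -90.0),
    ("forearm_supination", 90.0),
    ("forearm_pronation", -90.0),
]

_MOVEMENT_CHANNEL = {
    "wrist_extension": "wrist_flexion",
    "forearm_pronation": "forearm_supination",
}


def run_validity_suite(
    error_model=None,
    seed: int = 0,
    movements: Optional[List[Tuple[str, float]]] = None,
    side: str = "right",
    calibration_pose: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """In-silico rigid-arm validity test.

    Simulates a 90-degree movement per tested joint (shoulder flexion and
    abduction, elbow flexion, wrist flexion/extension and forearm
    pronation/supination), runs the full pipeline on each scene and
    reports, at the target position: the reconstructed angle, its
    ground-truth value, their absolute deviation, and the largest
    off-axis angle among the joints that should not have moved.
    """
    from .synthetic_rig import (
        SensorErrorModel,
        make_scene,
        make_single_joint_trajectory,
    )

    error_model = error_model if error_model is not None else SensorErrorModel.none()
    movements = movements or VALIDITY_MOVEMENTS
    rows = []
    for k, (movement, amplitude) in enumerate(movements):
        channel = _MOVEMENT_CHANNEL.get(movement, movement)
        traj = make_single_joint_trajectory(channel, amplitude)
        scene = make_scene(
            tasks={"movement": traj},
            error_model=error_model.with_seed(seed * 1009 + k),
            seed=seed * 1009 + k,
            side=side,
            calibration_pose=calibration_pose,
        )
        result = run_pipeline(
            scene.recordings, "movement", side=side, window_channel=channel
        )
        hold = scene.target_windows["movement"]
        truth_feats = extract_features(
            scene.truth_angles["movement"], TargetWindow(*hold)
        )
        measured = result.features.get(channel, math.nan)
        truth = truth_feats.get(channel, float(amplitude))
        off_axis = 0.0
        for name, val in result.features.items():
            if name == channel or not math.isfinite(val):
                continue
            off_axis = max(off_axis, abs(val - truth_feats.get(name, 0.0)))
        rows.append(
            {
                "movement": movement,
                "channel": channel,
                "amplitude_deg": amplitude,
                "measured_deg": measured,
                "truth_deg": truth,
                "abs_error_deg": abs(measured - truth),
                "max_off_axis_error_deg": off_axis,
            }
        )
    return pd.DataFrame(rows)
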
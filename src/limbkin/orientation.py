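"""Sensor orientation estimation with zero-angular-velocity drift removal.

The estimation pipeline per sensor is:

1. detect static intervals (gyro norm below 3 deg/s for at least a minimum
   duration);
2. remove gyroscope bias by linear interpolation of the per-interval mean
   bias between consecutive static intervals (zero-velocity update), and
   force the angular rate to exactly zero inside the static intervals;
3. fuse the corrected gyro with the accelerometer in a Madgwick-style
   gradient-descent filter: quaternion-rate integration of the gyro with a
   small inclination correction step toward the measured gravity direction,
   weighted by the gain ``beta``.  Heading evolves from the gyro alone (no
   magnetometer).

Orientations are quaternions of the sensor frame in the global frame
(scalar-first, Hamilton); composing with the sensor-to-segment calibration
on the right yields the segment orientation.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Tuple

import numpy as np

from .datamodel import GRAVITY, OrientationTrace, RawImuRecording, SegmentCalibration
from .rotations import quat_from_matrix, quat_multiply, quat_normalize

logger = logging.getLogger(__name__)

STATIC_THRESHOLD = math.radians(3.0)  # rad/s; below this the sensor is static
DEFAULT_MIN_STATIC_DURATION = 0.25  # s
DEFAULT_BETA = 0.033  # rad/s, filter gain

StaticInterval = Tuple[int, int]  # half-open [start, end), 0-based samples


def detect_static_periods(
    gyro: np.ndarray,
    fs: float,
    threshold: float = STATIC_THRESHOLD,
    min_duration: float = DEFAULT_MIN_STATIC_DURATION,
) -> List[StaticInterval]:
    """Maximal runs of samples with ``|omega| < threshold``, discarding runs
    shorter than ``min_duration`` seconds.  Returns sorted, disjoint,
    half-open index intervals."""
    gyro = np.asarray(gyro, dtype=float)
    if gyro.size == 0:
        raise ValueError("empty gyro stream")
    still = np.linalg.norm(gyro, axis=1) < threshold
    edges = np.flatnonzero(np.diff(still.astype(np.int8)))
    starts = list(edges[~still[edges]] + 1)
    ends = list(edges[still[edges]] + 1)
    if still[0]:
        starts.insert(0, 0)
    if still[-1]:
        ends.append(still.size)
    min_samples = int(np.ceil(min_duration * fs))
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_samples]


def correct_gyro_drift(
    gyro: np.ndarray, statics: List[StaticInterval]
) -> np.ndarray:
    """Remove slowly varying gyroscope bias using static intervals.

    The bias inside each static interval is its mean angular rate; between
    consecutive intervals the bias is linearly interpolated (anchored at
    the interval time-centroids, so a linearly ramping bias is removed
    exactly), and held constant before the first / after the last interval.
    Samples inside static intervals are forced to exactly zero.
    """
    gyro = np.asarray(gyro, dtype=float)
    if not statics:
        logger.warning("no static intervals: gyro passed through uncorrected")
        return gyro.copy()
    centroids = np.array([0.5 * (s + e - 1) for s, e in statics])
    biases = np.stack([gyro[s:e].mean(axis=0) for s, e in statics])
    idx = np.arange(gyro.shape[0], dtype=float)
    bias_t = np.column_stack(
        [np.interp(idx, centroids, biases[:, k]) for k in range(3)]
    )
    out = gyro - bias_t
    for s, e in statics:
        out[s:e] = 0.0
    return out


def _madgwick_step(q, gx, gy, gz, ax, ay, az, beta, dt):
    """One fused update; ``q`` is (w, x, y, z) of sensor-in-global.

    Predict-then-correct: the gyro quaternion rate is integrated first and
    the normalized gradient step toward the measured gravity direction is
    evaluated at the *predicted* quaternion, so a steadily rotating sensor
    carries no one-sample correction lag.
    """
    w, x, y, z = q
    # predictor: 0.5 * q ⊗ (0, omega), Euler step
    w1 = w + 0.5 * (-x * gx - y * gy - z * gz) * dt
    x1 = x + 0.5 * (w * gx + y * gz - z * gy) * dt
    y1 = y + 0.5 * (w * gy - x * gz + z * gx) * dt
    z1 = z + 0.5 * (w * gz + x * gy - y * gx) * dt
    n = math.sqrt(w1 * w1 + x1 * x1 + y1 * y1 + z1 * z1)
    w, x, y, z = w1 / n, x1 / n, y1 / n, z1 / n

    if beta > 0.0 and not (ax == 0.0 and ay == 0.0 and az == 0.0):
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        ax, ay, az = ax / norm, ay / norm, az / norm
        # objective: predicted gravity direction in the sensor frame
        # (third row of R(q)) minus the measured unit accel
        f1 = 2.0 * (x * z - w * y) - ax
        f2 = 2.0 * (y * z + w * x) - ay
        f3 = 1.0 - 2.0 * (x * x + y * y) - az
        # gradient = J^T f
        sw = -2.0 * y * f1 + 2.0 * x * f2
        sx = 2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3
        sy = -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3
        sz = 2.0 * x * f1 + 2.0 * y * f2
        snorm = math.sqrt(sw * sw + sx * sx + sy * sy + sz * sz)
        if snorm > 0.0:
            step = beta * dt / snorm
            w -= step * sw
            x -= step * sx
            y -= step * sy
            z -= step * sz
            n = math.sqrt(w * w + x * x + y * y + z * z)
            w, x, y, z = w / n, x / n, y / n, z / n
    return (w, x, y, z)


def estimate_orientation(
    recording: RawImuRecording,
    q0: np.ndarray,
    beta: float = DEFAULT_BETA,
    gyro_override: Optional[np.ndarray] = None,
) -> OrientationTrace:
    """Estimate the sensor-in-global orientation trace.

    ``q0`` is the initial orientation (from the global-frame alignment at
    the initial posture).  ``gyro_override`` supplies a drift-corrected
    gyro stream; by default the recording's gyro is used as-is.  Samples
    whose accelerometer norm falls outside [0.5 g, 1.5 g] skip the
    inclination correction (gyro-only) and are counted in the log.
    """
    gyro = recording.gyro if gyro_override is None else np.asarray(gyro_override, float)
    accel = recording.accel
    time = recording.time
    n = time.shape[0]
    quats = np.empty((n, 4))
    q = tuple(quat_normalize(np.asarray(q0, dtype=float)))
    quats[0] = q
    lo, hi = 0.5 * GRAVITY, 1.5 * GRAVITY
    skipped = 0
    for i in range(1, n):
        dt = time[i] - time[i - 1]
        ax, ay, az = accel[i]
        anorm = math.sqrt(ax * ax + ay * ay + az * az)
        if not (lo <= anorm <= hi):
            skipped += 1
            ax = ay = az = 0.0  # disables the correction step
        q = _madgwick_step(q, gyro[i][0], gyro[i][1], gyro[i][2],
                           ax, ay, az, beta, dt)
        quats[i] = q
    if skipped:
        logger.info(
            "%s: skipped accel correction at %d/%d samples (norm outside "
            "[0.5g, 1.5g])", recording.placement.label, skipped, n,
        )
    return OrientationTrace(recording.placement, time, quats, "sensor_in_global")


def segment_orientation(
    sensor_trace: OrientationTrace, calib: SegmentCalibration
) -> OrientationTrace:
    """Compose the sensor trace with the sensor-to-segment calibration:
    per sample ``g_R_seg = g_R_s @ s_R_seg``."""
    if sensor_trace.frame != "sensor_in_global":
        raise ValueError("input trace must be in the sensor_in_global frame")
    sensor_trace.check_placement(calib)
    q_cal = quat_from_matrix(calib.s_R_seg)
    quats = quat_normalize(quat_multiply(sensor_trace.quat, q_cal))
    return OrientationTrace(
        sensor_trace.placement, sensor_trace.time, quats, "segment_in_global"
    )
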
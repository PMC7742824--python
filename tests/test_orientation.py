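import math

import numpy as np
import pytest

from limbkin.datamodel import OrientationTrace, RawImuRecording, SensorPlacement
from limbkin.orientation import (
    correct_gyro_drift,
    detect_static_periods,
    estimate_orientation,
    segment_orientation,
)
from limbkin.rotations import (
    quat_angle_deg,
    quat_conjugate,
    quat_from_axis_angle,
    quat_from_matrix,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    random_rotation,
)

FS = 200.0
G = 9.81


class TestStaticDetection:
    def test_all_zero_gyro_is_one_interval(self):
        assert detect_static_periods(np.zeros((400, 3)), FS) == [(0, 400)]

    def test_rate_above_threshold_yields_empty_list(self):
        gyro = np.tile([0.1, 0.0, 0.0], (400, 1))  # ~5.7 deg/s > 3 deg/s
        assert detect_static_periods(gyro, FS) == []

    def test_still_move_still_intervals(self):
        gyro = np.zeros((600, 3))
        gyro[200:400, 1] = 1.0
        assert detect_static_periods(gyro, FS) == [(0, 200), (400, 600)]

    def test_short_runs_discarded(self):
        gyro = np.tile([1.0, 0.0, 0.0], (400, 1))
        gyro[100:130] = 0.0  # 0.15 s < 0.25 s minimum
        assert detect_static_periods(gyro, FS) == []


class TestDriftCorrection:
    def test_constant_bias_fully_removed(self):
        bias = np.array([0.011, -0.007, 0.004])
        gyro = np.tile(bias, (600, 1))
        statics = [(0, 200), (400, 600)]
        corrected = correct_gyro_drift(gyro, statics)
        assert np.abs(corrected).max() < 1e-12

    def test_linearly_ramping_bias_fully_removed(self):
        # bias ramps from b1 to b2 across the record; interpolation between
        # the static centroids matches a linear ramp exactly
        t = np.arange(600)[:, None]
        b1, b2 = np.array([0.01, 0.0, -0.02]), np.array([0.04, 0.01, 0.02])
        gyro = b1 + (b2 - b1) * t / 599.0
        corrected = correct_gyro_drift(gyro, [(0, 200), (400, 600)])
        assert np.abs(corrected).max() < 1e-9

    def test_true_rotation_preserved_under_constant_bias(self):
        """90 deg of true rotation between two statics survives bias removal;
        oracle: trapezoidal integral of the corrected rate."""
        n_still, n_move = 300, 400
        t_move = np.arange(n_move) / FS
        duration = (n_move - 1) / FS
        # half-sine rate profile integrating to pi/2
        rate = (math.pi / 2) * (math.pi / (2 * duration)) * np.sin(
            math.pi * t_move / duration
        )
        gyro = np.zeros((n_still * 2 + n_move, 3))
        gyro[n_still:n_still + n_move, 2] = rate
        bias = np.array([0.012, -0.008, 0.015])
        statics = detect_static_periods(gyro + bias, FS)
        corrected = correct_gyro_drift(gyro + bias, statics)
        integral = np.trapezoid(corrected[:, 2], dx=1.0 / FS)
        assert math.degrees(integral) == pytest.approx(90.0, abs=0.1)

    def test_no_statics_passes_through_with_warning(self, caplog):
        gyro = np.tile([1.0, 0.0, 0.0], (100, 1))
        with caplog.at_level("WARNING"):
            out = correct_gyro_drift(gyro, [])
        assert np.array_equal(out, gyro)
        assert "uncorrected" in caplog.text


def _recording_from_truth(q_path, fs=FS):
    """Synthesize a noise-free recording following a quaternion path."""
    n = q_path.shape[0]
    t = np.arange(n) / fs
    accel = quat_rotate(quat_conjugate(q_path), np.array([0.0, 0.0, G]))
    # body rates from finite differences of the true path
    gyro = np.zeros((n, 3))
    for i in range(1, n):
        dq = quat_multiply(quat_conjugate(q_path[i - 1]), q_path[i])
        dq = dq if dq[0] >= 0 else -dq
        angle = 2.0 * math.acos(min(dq[0], 1.0))
        axis = dq[1:]
        norm = np.linalg.norm(axis)
        gyro[i] = (angle / (1.0 / fs)) * axis / norm if norm > 0 else 0.0
    return RawImuRecording(SensorPlacement("upper_arm"), t, gyro, accel)


class TestOrientationEstimation:
    def test_static_identity_stays_identity(self):
        n = 400
        t = np.arange(n) / FS
        rec = RawImuRecording(
            SensorPlacement("sternum"), t, np.zeros((n, 3)),
            np.tile([0.0, 0.0, G], (n, 1)),
        )
        trace = estimate_orientation(rec, [1, 0, 0, 0])
        assert quat_angle_deg(trace.quat[-1], np.array([1, 0, 0, 0])) < 1e-9

    def test_noise_free_rotation_tracks_truth_within_tenth_degree(self):
        """90 deg about a horizontal axis at 45 deg/s; the exact-integration
        oracle is the constructed quaternion path itself."""
        n = int(2 * FS) + 1
        angles = np.linspace(0.0, math.pi / 2, n)
        q_path = quat_from_axis_angle([0.0, 1.0, 0.0], angles)
        rec = _recording_from_truth(q_path)
        trace = estimate_orientation(rec, q_path[0])
        # inclination: angle between predicted and true gravity directions
        up_est = quat_rotate(quat_conjugate(trace.quat[-1]), np.array([0.0, 0.0, 1.0]))
        up_true = quat_rotate(quat_conjugate(q_path[-1]), np.array([0.0, 0.0, 1.0]))
        incl = math.degrees(math.acos(float(np.clip(up_est @ up_true, -1, 1))))
        assert incl < 0.1

    def test_beta_zero_equals_pure_quaternion_integration(self):
        """With the corrective gain off, the filter is exactly quaternion-rate
        (Euler) integration of the gyro; independent oracle reimplementation."""
        rng = np.random.default_rng(3)
        n = 400
        t = np.arange(n) / FS
        gyro = rng.normal(scale=0.8, size=(n, 3))
        accel = np.tile([0.0, 0.0, G], (n, 1))
        rec = RawImuRecording(SensorPlacement("hand"), t, gyro, accel)
        trace = estimate_orientation(rec, [1, 0, 0, 0], beta=0.0)
        q = np.array([1.0, 0.0, 0.0, 0.0])
        dt = 1.0 / FS
        for i in range(1, n):
            w = gyro[i]
            qdot = 0.5 * quat_multiply(q, np.array([0.0, *w]))
            q = quat_normalize(q + qdot * dt)
        assert np.abs(trace.quat[-1] - q).max() < 1e-9

    def test_accel_correction_pulls_inclination_back_under_gyro_bias(self):
        """A truly static sensor with a biased gyro: inclination error must
        stay bounded near zero while (unobservable) heading drifts."""
        n = int(30 * FS)
        t = np.arange(n) / FS
        gyro = np.tile([0.02, 0.015, 0.02], (n, 1))  # uncorrected bias
        accel = np.tile([0.0, 0.0, G], (n, 1))
        rec = RawImuRecording(SensorPlacement("forearm"), t, gyro, accel)
        trace = estimate_orientation(rec, [1, 0, 0, 0])
        up_est = quat_rotate(
            quat_conjugate(trace.quat[-1]), np.array([0.0, 0.0, 1.0])
        )
        incl = math.degrees(math.acos(float(np.clip(up_est[2], -1, 1))))
        heading_drift = quat_angle_deg(trace.quat[-1], np.array([1, 0, 0, 0]))
        assert incl < 1.0
        assert heading_drift > 5.0  # the gyro bias does drift the heading

    def test_out_of_range_accel_samples_skip_correction(self, caplog):
        n = 400
        t = np.arange(n) / FS
        accel = np.tile([0.0, 0.0, G], (n, 1))
        accel[100:200] *= 3.0  # far outside [0.5 g, 1.5 g]
        rec = RawImuRecording(SensorPlacement("thumb"), t, np.zeros((n, 3)), accel)
        with caplog.at_level("INFO"):
            trace = estimate_orientation(rec, [1, 0, 0, 0])
        assert "skipped accel correction at 100" in caplog.text
        assert quat_angle_deg(trace.quat[-1], np.array([1, 0, 0, 0])) < 1e-6


class TestSegmentComposition:
    def _trace(self, rng, n=50):
        q = quat_from_matrix(random_rotation(rng))
        qs = np.array([
            quat_normalize(quat_multiply(q, quat_from_axis_angle([1, 0, 0], 0.01 * i)))
            for i in range(n)
        ])
        return OrientationTrace(
            SensorPlacement("forearm"), np.arange(n) / FS, qs, "sensor_in_global"
        )

    def test_identity_calibration_is_identity_composition(self, rng):
        from limbkin.datamodel import SegmentCalibration

        trace = self._trace(rng)
        calib = SegmentCalibration(SensorPlacement("forearm"), np.eye(3))
        out = segment_orientation(trace, calib)
        assert np.allclose(out.quat, trace.quat, atol=1e-12)
        assert out.frame == "segment_in_global"

    def test_composition_with_inverse_recovers_input(self, rng):
        from limbkin.datamodel import SegmentCalibration

        R = random_rotation(rng)
        trace = self._trace(rng)
        calib = SegmentCalibration(SensorPlacement("forearm"), R)
        calib_inv = SegmentCalibration(SensorPlacement("forearm"), R.T)
        out = segment_orientation(trace, calib)
        sensor_like = OrientationTrace(
            out.placement, out.time, out.quat, "sensor_in_global"
        )
        back = segment_orientation(sensor_like, calib_inv)
        assert np.max(quat_angle_deg(back.quat, trace.quat)) < 1e-9

    def test_placement_mismatch_raises(self, rng):
        from limbkin.datamodel import SegmentCalibration
        from limbkin.errors import PlacementMismatchError

        trace = self._trace(rng)
        calib = SegmentCalibration(SensorPlacement("hand"), np.eye(3))
        with pytest.raises(PlacementMismatchError):
            segment_orientation(trace, calib)

    def test_quaternion_norm_preserved(self, rng):
        from limbkin.datamodel import SegmentCalibration

        trace = self._trace(rng)
        calib = SegmentCalibration(SensorPlacement("forearm"), random_rotation(rng))
        out = segment_orientation(trace, calib)
        assert np.abs(np.linalg.norm(out.quat, axis=1) - 1.0).max() < 1e-9
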
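import math

import numpy as np
import pytest

from limbkin.calibration import (
    AxisEstimate,
    CalibrationProtocol,
    build_segment_frame,
    calibrate_all,
    define_global_frame,
    estimate_axis_dynamic,
    estimate_axis_static,
)
from limbkin.datamodel import LabelledRecordingSet, RawImuRecording, SensorPlacement
from limbkin.errors import (
    CollinearAxesError,
    DegenerateAxisError,
    DegenerateHorizontalAxisError,
    NoMovementError,
)
from limbkin.rotations import axis_angle_matrix, is_rotation_matrix, rotation_angle_deg
from limbkin.synthetic_rig import SensorErrorModel, make_scene


class TestStaticAxis:
    def test_constant_gravity_along_z(self):
        accel = np.tile([0.0, 0.0, 9.81], (300, 1))
        est = estimate_axis_static(accel)
        assert np.allclose(est.vector, [0, 0, 1], atol=1e-12)
        assert est.source == "accelerometer_static"

    def test_median_rejects_single_outlier(self):
        accel = np.tile([0.0, 0.0, 9.81], (201, 1))
        accel[100] = [50.0, 0.0, 0.0]
        est = estimate_axis_static(accel)
        assert np.allclose(est.vector, [0, 0, 1], atol=1e-12)

    def test_componentwise_median_of_alternating_samples(self):
        # median per component: x -> 0 (average of the two middle values
        # of an equal mix of +1/-1), y -> 0, z -> 9.81; direct enumeration
        accel = np.array([[1.0, 0.0, 9.81], [-1.0, 0.0, 9.81]] * 50)
        est = estimate_axis_static(accel)
        assert np.allclose(est.vector, [0, 0, 1], atol=1e-12)

    def test_free_fall_is_degenerate(self):
        with pytest.raises(DegenerateAxisError):
            estimate_axis_static(np.full((300, 3), 0.01))

    def test_motion_during_static_item_rejected(self):
        accel = np.tile([0.0, 0.0, 9.81], (300, 1))
        gyro = np.tile([0.5, 0.0, 0.0], (300, 1))  # ~29 deg/s, not still
        with pytest.raises(DegenerateAxisError):
            estimate_axis_static(accel, gyro)


class TestDynamicAxis:
    def test_pure_single_axis_rotation(self):
        gyro = np.tile([0.0, 1.0, 0.0], (400, 1))
        est = estimate_axis_dynamic(gyro)
        assert np.allclose(est.vector, [0, 1, 0], atol=1e-12)

    def test_noisy_rotation_axis_within_one_degree(self):
        rng = np.random.default_rng(7)
        gyro = np.tile([0.0, 1.0, 0.0], (400, 1)) + rng.normal(
            scale=0.01, size=(400, 3)
        )
        est = estimate_axis_dynamic(gyro)
        ang = math.degrees(math.acos(float(np.clip(est.vector[1], -1, 1))))
        assert ang < 1.0

    def test_sign_follows_initial_rotation_direction(self):
        # flex-then-return: positive rotation first, then the reverse;
        # the estimate must keep the initial hemisphere
        gyro = np.concatenate(
            [np.tile([0.0, 1.0, 0.0], (200, 1)), np.tile([0.0, -1.0, 0.0], (200, 1))]
        )
        est = estimate_axis_dynamic(gyro)
        assert np.allclose(est.vector, [0, 1, 0], atol=1e-12)

    def test_no_movement_detected(self):
        with pytest.raises(NoMovementError):
            estimate_axis_dynamic(np.full((400, 3), 0.01))


class TestSegmentFrame:
    def test_orthogonal_axes_give_identity(self):
        a = AxisEstimate(np.array([1.0, 0, 0]), "accelerometer_static", "neutral")
        b = AxisEstimate(np.array([0.0, 1, 0]), "gyroscope_dynamic", "flex")
        cal = build_segment_frame(a, b, "x", "y")
        assert np.allclose(cal.s_R_seg, np.eye(3), atol=1e-12)

    def test_gram_schmidt_redefinition_of_second_axis(self):
        # by hand: z = x cross b / |..| = (0,0,1); y = z cross x = (0,1,0)
        b_raw = np.array([0.1, 0.995, 0.0])
        a = AxisEstimate(np.array([1.0, 0, 0]), "accelerometer_static", "neutral")
        b = AxisEstimate(b_raw / np.linalg.norm(b_raw), "gyroscope_dynamic", "flex")
        cal = build_segment_frame(a, b, "x", "y", redefine="b")
        expect = np.eye(3)
        assert np.allclose(cal.s_R_seg, expect, atol=1e-9)
        assert cal.provenance["redefined"] == "y"

    def test_near_collinear_axes_rejected_with_angle(self):
        a = AxisEstimate(np.array([1.0, 0, 0]), "accelerometer_static", "i")
        v = np.array([math.cos(math.radians(10)), math.sin(math.radians(10)), 0])
        b = AxisEstimate(v, "gyroscope_dynamic", "j")
        with pytest.raises(CollinearAxesError) as err:
            build_segment_frame(a, b, "x", "y")
        assert err.value.angle_deg == pytest.approx(10.0, abs=1e-6)

    def test_result_is_always_proper_rotation(self, rng):
        for _ in range(50):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            a /= np.linalg.norm(a)
            b /= np.linalg.norm(b)
            ang = math.degrees(math.acos(abs(float(np.clip(a @ b, -1, 1)))))
            if ang < 35.0:
                continue
            cal = build_segment_frame(
                AxisEstimate(a, "accelerometer_static", "i"),
                AxisEstimate(b, "gyroscope_dynamic", "j"),
                "x", "z",
            )
            assert is_rotation_matrix(cal.s_R_seg, tol=1e-9)


class TestCalibrateAll:
    def test_identity_mounting_gives_identity_calibration(self):
        from limbkin.synthetic_rig import identity_mountings

        scene = make_scene(
            mountings=identity_mountings(), error_model=SensorErrorModel.none(), seed=0
        )
        cal = calibrate_all(scene.recordings)
        for label, c in cal.items():
            assert np.allclose(c.s_R_seg, np.eye(3), atol=1e-6), label

    def test_random_mountings_recovered_noise_free(self):
        scene = make_scene(error_model=SensorErrorModel.none(), seed=21)
        cal = calibrate_all(scene.recordings)
        assert len(cal) == 8
        for label, c in cal.items():
            err = rotation_angle_deg(c.s_R_seg, np.linalg.inv(scene.mountings[label]))
            assert err < 0.5, label

    def test_left_side_mirrored_scene_recovered(self):
        scene = make_scene(error_model=SensorErrorModel.none(), seed=22, side="left")
        cal = calibrate_all(scene.recordings, CalibrationProtocol.default("left"))
        for label, c in cal.items():
            err = rotation_angle_deg(c.s_R_seg, np.linalg.inv(scene.mountings[label]))
            assert err < 0.5, label

    def test_scale_invariance_of_accelerometer_units(self, noise_free_elbow_scene):
        scene = noise_free_elbow_scene
        scaled = LabelledRecordingSet()
        for item in scene.recordings.labels():
            for label, rec in scene.recordings[item].items():
                scaled.add(
                    item,
                    RawImuRecording(rec.placement, rec.time, rec.gyro,
                                    rec.accel * 2.5, rec.gyro_rate, rec.accel_rate),
                )
        cal1 = calibrate_all(scene.recordings)
        cal2 = calibrate_all(scaled)
        for label in cal1:
            assert np.allclose(cal1[label].s_R_seg, cal2[label].s_R_seg, atol=1e-12)


def _single_sensor_set(accel_neutral, hip_axis, fs=200.0):
    """A minimal two-item set for one sensor, for global-frame tests."""
    recset = LabelledRecordingSet()
    p = SensorPlacement("sternum")
    n = int(5 * fs)
    t = np.arange(n) / fs
    recset.add(
        "neutral_pose",
        RawImuRecording(p, t, np.zeros((n, 3)), np.tile(accel_neutral, (n, 1))),
    )
    gyro = np.zeros((n, 3))
    third = n // 3
    gyro[third:2 * third] = hip_axis
    recset.add(
        "hip_flexion",
        RawImuRecording(p, t, gyro, np.tile(accel_neutral, (n, 1))),
    )
    return recset


class TestGlobalFrame:
    def test_gravity_up_and_hip_on_y_gives_identity(self):
        recset = _single_sensor_set([0.0, 0.0, 9.81], [0.0, 1.0, 0.0])
        alignment = define_global_frame(recset)
        assert np.allclose(alignment["sternum"], np.eye(3), atol=1e-9)

    def test_heading_difference_between_sensors_is_recovered(self):
        R = axis_angle_matrix([0, 0, 1], math.radians(90.0))
        recset = _single_sensor_set([0.0, 0.0, 9.81], [0.0, 1.0, 0.0])
        # second sensor physically rotated 90 deg about the vertical:
        # it measures the same gravity and the hip axis R^T y
        p2 = SensorPlacement("shoulder")
        base = recset["neutral_pose"]["sternum"]
        recset.add("neutral_pose", RawImuRecording(
            p2, base.time, base.gyro, base.accel))
        hip = recset["hip_flexion"]["sternum"]
        recset.add("hip_flexion", RawImuRecording(
            p2, hip.time, hip.gyro @ R, hip.accel))
        alignment = define_global_frame(recset)
        rel = alignment["shoulder"] @ alignment["sternum"].T
        # g_R_s2 = g_R_s1 @ R  =>  relative heading rotation equals R
        assert rotation_angle_deg(alignment["shoulder"], alignment["sternum"] @ R.T) < 1e-6 or \
            rotation_angle_deg(rel, R) < 1e-6

    def test_hip_axis_near_vertical_rejected(self):
        recset = _single_sensor_set([0.0, 0.0, 9.81], [0.0, 0.1, 0.995])
        with pytest.raises(DegenerateHorizontalAxisError):
            define_global_frame(recset)

    def test_simulator_scene_gravity_spread_below_tenth_degree(
        self, noise_free_elbow_scene
    ):
        alignment = define_global_frame(noise_free_elbow_scene.recordings)
        assert alignment.gravity_spread_deg < 0.1

    def test_common_scene_rotation_shifts_all_alignments_equally(self):
        """Rotating the whole scene (a different subject heading) rotates
        every sensor's alignment by the same heading rotation."""
        s0 = make_scene(error_model=SensorErrorModel.none(), seed=33)
        s1 = make_scene(error_model=SensorErrorModel.none(), seed=33,
                        heading_deg=40.0)
        a0 = define_global_frame(s0.recordings)
        a1 = define_global_frame(s1.recordings)
        for label in a0.rotations:
            # sensor streams are heading-invariant, so the *estimated*
            # alignments coincide; the true orientations differ by the
            # common rotation, which cancels in every relative quantity
            assert np.allclose(a0[label], a1[label], atol=1e-12)
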
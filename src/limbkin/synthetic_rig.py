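"""Rigid articulated upper-limb simulator and IMU signal synthesis.

The simulator is the in-silico counterpart of a rigid arm model: an
8-segment kinematic tree (sternum -> shoulder -> upper arm -> forearm ->
hand -> thumb/index/middle) whose joint channels are smooth functions of
time.  From ground-truth segment orientations it synthesizes the raw IMU
streams — gyroscope at 200 Hz and accelerometer at 100 Hz, with
configurable bias and noise — for sensors mounted on the segments with
arbitrary (by default randomized) mounting rotations, together with the
calibration items the reconstruction pipeline needs.  With zero noise the
synthesized gyro equals the true segment angular velocity expressed in the
sensor frame to machine precision.

Movement profiles are minimum-jerk rise / hold / return curves; the
accelerometer carries the gravity-only specific force by default (the
protocol's movements are slow and the fusion filter uses the
accelerometer purely as an inclination reference).

Joint conventions mirror the reconstruction side: at all-zero joint angles
the chain is in the neutral pose (arm along the body, fingers extended,
every segment frame x up, y lateral, z anterior); flexion channels rotate
about +y, abduction about -z and supination about -x for a right arm, with
mirrored signs on the left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np

from .datamodel import (
    ACCEL_RATE_HZ,
    CHANNELS,
    GRAVITY,
    GYRO_RATE_HZ,
    HIP_FLEXION_ITEM,
    NEUTRAL_ITEM,
    JointAngleTrace,
    LabelledRecordingSet,
    OrientationTrace,
    PLACEMENTS,
    RawImuRecording,
    SensorPlacement,
)
from .rotations import (
    quat_from_axis_angle,
    quat_from_matrix,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    random_rotation,
)

#: all simulator channels (joint channels plus the trunk used for the
#: hip-flexion calibration movement)
SIM_CHANNELS = CHANNELS + ("trunk_flexion",)

_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])
_X = np.array([1.0, 0.0, 0.0])


def _chain_axes(side: str) -> Dict[str, List[Tuple[str, np.ndarray]]]:
    """Per-segment ordered intrinsic joint rotations (channel, axis)."""
    lat = -1.0 if side == "right" else 1.0  # sign of abduction/supination axes
    return {
        # trunk flexion rotates about the hip-flexion axis, which is the
        # negative medio-lateral axis of a right-arm frame
        "sternum": [("trunk_flexion", -_Y if side == "right" else _Y)],
        "shoulder": [],
        "upper_arm": [("shoulder_flexion", _Y), ("shoulder_abduction", lat * _Z)],
        "forearm": [("elbow_flexion", _Y), ("forearm_supination", lat * _X)],
        "hand": [("wrist_flexion", _Y)],
        "thumb": [("thumb_flexion", _Y)],
        "index": [("index_flexion", _Y)],
        "middle": [("middle_flexion", _Y)],
    }


_PARENT = {
    "sternum": None,
    "shoulder": "sternum",
    "upper_arm": "shoulder",
    "forearm": "upper_arm",
    "hand": "forearm",
    "thumb": "hand",
    "index": "hand",
    "middle": "hand",
}

#: body frame at the neutral pose expressed in the global frame
#: (x up, y along the hip-flexion axis flipped for side, z anterior);
#: global: x anterior, y hip-flexion axis (subject's left), z up.
def _g_R_body(side: str) -> np.ndarray:
    x_up = np.array([0.0, 0.0, 1.0])
    y_lat = np.array([0.0, -1.0, 0.0]) if side == "right" else np.array([0.0, 1.0, 0.0])
    z_ant = np.cross(x_up, y_lat)
    return np.column_stack([x_up, y_lat, z_ant])


def minimum_jerk(tau: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk unit profile s(tau) and ds/dtau on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return s, ds


@dataclass(frozen=True)
class MovePhase:
    """Rise-hold-return profile: amplitude (deg) with minimum-jerk edges."""

    amplitude: float
    t_start: float
    rise: float
    hold: float
    fall: Optional[float] = None

    def angle_rate(self, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        fall = self.rise if self.fall is None else self.fall
        a = math.radians(self.amplitude)
        ang = np.zeros_like(t)
        rate = np.zeros_like(t)
        s_up, ds_up = minimum_jerk((t - self.t_start) / self.rise)
        ang += a * s_up
        m_up = (t >= self.t_start) & (t < self.t_start + self.rise)
        rate[m_up] = a * ds_up[m_up] / self.rise
        t_down = self.t_start + self.rise + self.hold
        if fall > 0:
            s_dn, ds_dn = minimum_jerk((t - t_down) / fall)
            ang -= a * s_dn
            m_dn = (t >= t_down) & (t < t_down + fall)
            rate[m_dn] = -a * ds_dn[m_dn] / fall
        return ang, rate

    @property
    def hold_interval(self) -> Tuple[float, float]:
        return (self.t_start + self.rise, self.t_start + self.rise + self.hold)


@dataclass(frozen=True)
class OscillationPhase:
    """Smooth sinusoidal oscillation with minimum-jerk amplitude envelope."""

    amplitude: float  # deg, peak
    t_start: float
    duration: float
    cycles: float = 3.0
    ramp: float = 0.5  # s, envelope rise/fall

    def angle_rate(self, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        a = math.radians(self.amplitude)
        w = 2.0 * math.pi * self.cycles / self.duration
        tl = t - self.t_start
        inside = (tl >= 0.0) & (tl <= self.duration)
        env, denv = minimum_jerk(tl / self.ramp)
        env_out, denv_out = minimum_jerk((self.duration - tl) / self.ramp)
        e = np.where(tl < self.ramp, env, 1.0)
        de = np.where(tl < self.ramp, denv / self.ramp, 0.0)
        tail = self.duration - tl < self.ramp
        e = np.where(tail, env_out, e)
        de = np.where(tail, -denv_out / self.ramp, de)
        ang = np.where(inside, a * e * np.sin(w * tl), 0.0)
        rate = np.where(
            inside, a * (de * np.sin(w * tl) + e * w * np.cos(w * tl)), 0.0
        )
        return ang, rate


Trajectory = Dict[str, List]


@dataclass
class TrajectoryTiming:
    lead: float = 2.0  # s static before the movement
    rise: float = 2.0
    hold: float = 2.0
    tail: float = 2.0  # s static after return
    fs: float = GYRO_RATE_HZ

    @property
    def duration(self) -> float:
        return self.lead + self.rise + self.hold + self.rise + self.tail


def make_task_trajectory(
    task: int,
    amplitude: float = 90.0,
    timing: Optional[TrajectoryTiming] = None,
    synergy_gain: float = 0.0,
    wrist_amplitude: float = 50.0,
) -> Tuple[Trajectory, TrajectoryTiming, Tuple[float, float]]:
    """Joint-channel phase lists for one protocol task.

    Task templates (ideal performer; all other channels stay at zero):

    1. hand-to-ear within the flexor synergy — shoulder abduction to the
       amplitude with coupled elbow flexion (90 deg) and forearm
       supination (45 deg);
    2. shoulder flexion to the amplitude with the elbow extended;
    3. shoulder abduction to the amplitude, elbow extended, forearm
       pronated;
    4. shoulder flexion to 70 deg held while the wrist oscillates between
       flexion and extension.

    ``synergy_gain`` emulates the pathological flexor synergy: tasks 2-4
    add elbow flexion (gain x primary amplitude) and shoulder abduction
    (half that) coupled to the primary movement.  Returns the trajectory,
    the timing actually used, and the ground-truth target (hold) interval.
    """
    if not 0.0 < abs(amplitude) < 180.0:
        raise ValueError("amplitude must be in (0, 180) degrees")
    timing = timing or TrajectoryTiming()
    if timing.rise <= 0 or timing.hold <= 0:
        raise ValueError("rise and hold durations must be positive")
    t0, rise, hold = timing.lead, timing.rise, timing.hold
    main = MovePhase(amplitude, t0, rise, hold)
    traj: Trajectory = {ch: [] for ch in SIM_CHANNELS}
    if task == 1:
        traj["shoulder_abduction"].append(main)
        traj["elbow_flexion"].append(MovePhase(90.0, t0, rise, hold))
        traj["forearm_supination"].append(MovePhase(45.0, t0, rise, hold))
    elif task == 2:
        traj["shoulder_flexion"].append(main)
    elif task == 3:
        traj["shoulder_abduction"].append(main)
    elif task == 4:
        main = MovePhase(70.0, t0, rise, hold)
        traj["shoulder_flexion"].append(main)
        traj["wrist_flexion"].append(
            OscillationPhase(wrist_amplitude, t0 + rise, hold)
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    if synergy_gain > 0.0 and task != 1:
        primary = main.amplitude
        traj["elbow_flexion"].append(
            MovePhase(synergy_gain * primary, t0, rise, hold)
        )
        traj["shoulder_abduction"].append(
            MovePhase(0.5 * synergy_gain * primary, t0, rise, hold)
        )
    return traj, timing, main.hold_interval


def make_single_joint_trajectory(
    channel: str,
    amplitude: float = 90.0,
    timing: Optional[TrajectoryTiming] = None,
) -> Tuple[Trajectory, TrajectoryTiming, Tuple[float, float]]:
    """A single 90-degree-style movement on one joint channel — the
    building block of the rigid-model validity test."""
    timing = timing or TrajectoryTiming()
    phase = MovePhase(amplitude, timing.lead, timing.rise, timing.hold)
    traj: Trajectory = {ch: [] for ch in SIM_CHANNELS}
    if channel not in traj:
        raise ValueError(f"unknown channel {channel!r}")
    traj[channel].append(phase)
    return traj, timing, phase.hold_interval


def evaluate_trajectory(
    traj: Trajectory, time: np.ndarray
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Angles (rad) and rates (rad/s) for every simulator channel."""
    angles = {}
    rates = {}
    for ch in SIM_CHANNELS:
        a = np.zeros_like(time)
        r = np.zeros_like(time)
        for phase in traj.get(ch, []):
            pa, pr = phase.angle_rate(time)
            a += pa
            r += pr
        angles[ch] = a
        rates[ch] = r
    return angles, rates


@dataclass(frozen=True)
class SensorErrorModel:
    """Stochastic error model of one IMU pair.

    Gyro bias is a constant vector of norm ``gyro_bias`` with a
    per-sensor random direction (plus an optional linear drift ramp of
    ``gyro_drift_rate`` rad/s per second along the same direction); noise
    terms are white and Gaussian.  The same seed reproduces identical
    streams.
    """

    gyro_bias: float = 0.01  # rad/s
    gyro_noise_sd: float = 0.005  # rad/s
    accel_bias: float = 0.0  # m/s^2
    accel_noise_sd: float = 0.05  # m/s^2
    gyro_drift_rate: float = 0.0  # rad/s per s
    seed: int = 0

    def __post_init__(self):
        if self.gyro_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def none(cls) -> "SensorErrorModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0)

    @classmethod
    def default(cls, seed: int = 0) -> "SensorErrorModel":
        return cls(seed=seed)

    def with_seed(self, seed: int) -> "SensorErrorModel":
        return replace(self, seed=seed)


@dataclass
class SyntheticScene:
    """Ground truth plus the IMU streams synthesized from it."""

    side: str
    time: np.ndarray
    recordings: LabelledRecordingSet
    mountings: Dict[str, np.ndarray]  # seg_R_sensor per placement
    truth_orientations: Dict[str, Dict[str, OrientationTrace]]  # item -> segment
    truth_angles: Dict[str, JointAngleTrace]  # item -> trace (degrees)
    target_windows: Dict[str, Tuple[float, float]]  # task item -> hold interval
    error_model: SensorErrorModel = field(default_factory=SensorErrorModel.none)


def chain_kinematics(
    angles: Mapping[str, np.ndarray],
    rates: Mapping[str, np.ndarray],
    side: str = "right",
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Forward kinematics of the rigid chain.

    Returns per-segment orientation quaternions (segment in global, (N, 4))
    and angular velocities in the global frame (N, 3).
    """
    axes = _chain_axes(side)
    g_R_b = _g_R_body(side)
    q_base = quat_from_matrix(g_R_b)
    n = next(iter(angles.values())).shape[0]
    quats: Dict[str, np.ndarray] = {}
    omegas: Dict[str, np.ndarray] = {}
    for seg in PLACEMENTS:
        parent = _PARENT[seg]
        if parent is None:
            q = np.tile(q_base, (n, 1))
            w = np.zeros((n, 3))
        else:
            q = quats[parent].copy()
            w = omegas[parent].copy()
        for channel, axis in axes[seg]:
            theta = angles[channel]
            dtheta = rates[channel]
            # joint axis expressed in the global frame *before* this
            # rotation is applied
            axis_g = quat_rotate(q, axis)
            w = w + axis_g * dtheta[:, None]
            q = quat_normalize(quat_multiply(q, quat_from_axis_angle(axis, theta)))
        quats[seg] = q
        omegas[seg] = w
    return quats, omegas


def random_mountings(
    rng: np.random.Generator, placements=PLACEMENTS
) -> Dict[str, np.ndarray]:
    """Random sensor mounting rotation (seg_R_sensor) per placement."""
    return {p: random_rotation(rng) for p in placements}


def identity_mountings(placements=PLACEMENTS) -> Dict[str, np.ndarray]:
    return {p: np.eye(3) for p in placements}


def synthesize_item(
    label: str,
    traj: Trajectory,
    duration: float,
    mountings: Mapping[str, np.ndarray],
    error_model: SensorErrorModel,
    rng: np.random.Generator,
    side: str = "right",
    fs_gyro: float = GYRO_RATE_HZ,
    fs_accel: float = ACCEL_RATE_HZ,
) -> Tuple[Dict[str, RawImuRecording], Dict[str, OrientationTrace], np.ndarray]:
    """Synthesize the 8 sensor streams for one labelled item.

    Per sensor: gyro = mounting^-1 (true angular velocity in the sensor
    frame) + bias + noise at 200 Hz; accel = mounting^-1 expression of the
    gravity-only specific force, sampled at 100 Hz and carried on the
    gyro timebase by linear interpolation (mirroring the ingestion path).
    """
    n = int(round(duration * fs_gyro)) + 1
    time = np.arange(n) / fs_gyro
    angles, rates = evaluate_trajectory(traj, time)
    quats, omegas = chain_kinematics(angles, rates, side)

    accel_stride = max(int(round(fs_gyro / fs_accel)), 1)
    t_acc = time[::accel_stride]
    up = np.array([0.0, 0.0, GRAVITY])

    recordings: Dict[str, RawImuRecording] = {}
    truth: Dict[str, OrientationTrace] = {}
    for seg in PLACEMENTS:
        placement = SensorPlacement(seg, side=side)
        q_seg = quats[seg]
        truth[seg] = OrientationTrace(placement, time, q_seg, "segment_in_global")
        q_sensor = quat_normalize(
            quat_multiply(q_seg, quat_from_matrix(mountings[seg]))
        )
        # body-frame angular velocity and gravity direction
        q_conj = q_sensor * np.array([1.0, -1.0, -1.0, -1.0])
        gyro = quat_rotate(q_conj, omegas[seg])
        accel_full = quat_rotate(q_conj, np.broadcast_to(up, (n, 3)))
        accel = accel_full[::accel_stride].copy()

        if error_model.gyro_bias or error_model.gyro_drift_rate:
            direction = _unit(rng.normal(size=3))
            bias = error_model.gyro_bias * direction
            gyro = gyro + bias
            if error_model.gyro_drift_rate:
                gyro = gyro + np.outer(
                    time * error_model.gyro_drift_rate, direction
                )
        if error_model.gyro_noise_sd:
            gyro = gyro + rng.normal(scale=error_model.gyro_noise_sd, size=gyro.shape)
        if error_model.accel_bias:
            accel = accel + error_model.accel_bias * _unit(rng.normal(size=3))
        if error_model.accel_noise_sd:
            accel = accel + rng.normal(
                scale=error_model.accel_noise_sd, size=accel.shape
            )

        recordings[seg] = RawImuRecording.from_streams(
            placement, time, gyro, t_acc, accel,
            gyro_rate=fs_gyro, accel_rate=fs_accel,
        )
    return recordings, truth, time


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def calibration_items(
    calibration_pose: Optional[Mapping[str, float]] = None,
) -> Dict[str, Tuple[Trajectory, float]]:
    """Trajectories of the default calibration protocol's items.

    ``calibration_pose`` offsets joint channels (degrees) during *all*
    calibration items — e.g. ``{"elbow_flexion": 20}`` reproduces a
    subject who cannot fully extend the elbow during calibration.
    """
    pose = dict(calibration_pose or {})

    def static(duration: float) -> Tuple[Trajectory, float]:
        traj: Trajectory = {ch: [] for ch in SIM_CHANNELS}
        _apply_pose(traj, pose)
        return traj, duration

    def movement(channel: str, amplitude: float) -> Tuple[Trajectory, float]:
        timing = TrajectoryTiming(lead=1.5, rise=1.5, hold=0.5, tail=1.5)
        traj, _, _ = make_single_joint_trajectory(channel, amplitude, timing)
        _apply_pose(traj, pose)
        return traj, timing.duration

    items = {
        NEUTRAL_ITEM: static(5.0),
        HIP_FLEXION_ITEM: movement("trunk_flexion", 30.0),
        "arm_flexion": movement("shoulder_flexion", 45.0),
        "finger_flexion": _finger_item(pose),
    }
    return items


def _apply_pose(traj: Trajectory, pose: Mapping[str, float]) -> None:
    for ch, deg in pose.items():
        traj[ch].append(_ConstantOffset(deg))


def _finger_item(pose) -> Tuple[Trajectory, float]:
    timing = TrajectoryTiming(lead=1.5, rise=1.5, hold=0.5, tail=1.5)
    traj: Trajectory = {ch: [] for ch in SIM_CHANNELS}
    for ch in ("thumb_flexion", "index_flexion", "middle_flexion"):
        traj[ch].append(MovePhase(45.0, timing.lead, timing.rise, timing.hold))
    _apply_pose(traj, pose)
    return traj, timing.duration


@dataclass(frozen=True)
class _ConstantOffset:
    amplitude: float  # deg

    def angle_rate(self, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        a = math.radians(self.amplitude)
        return np.full_like(t, a), np.zeros_like(t)


def make_scene(
    tasks: Optional[Mapping[str, Tuple[Trajectory, TrajectoryTiming, Tuple[float, float]]]] = None,
    mountings: Optional[Mapping[str, np.ndarray]] = None,
    error_model: Optional[SensorErrorModel] = None,
    seed: int = 0,
    side: str = "right",
    calibration_pose: Optional[Mapping[str, float]] = None,
    heading_deg: float = 0.0,
) -> SyntheticScene:
    """Build a full scene: calibration items plus task recordings.

    ``tasks`` maps item labels (e.g. ``"task2"``) to trajectories from
    :func:`make_task_trajectory` / :func:`make_single_joint_trajectory`.
    ``heading_deg`` applies a common rotation of the whole scene about the
    vertical (the subject facing a different direction) — joint angles
    must be invariant to it.  Mounting rotations default to random ones
    drawn from the scene seed.
    """
    rng = np.random.default_rng(seed)
    error_model = error_model if error_model is not None else SensorErrorModel.none()
    if mountings is None:
        mountings = random_mountings(rng)
    tasks = tasks or {}

    recset = LabelledRecordingSet()
    truth_orient: Dict[str, Dict[str, OrientationTrace]] = {}
    truth_angles: Dict[str, JointAngleTrace] = {}
    target_windows: Dict[str, Tuple[float, float]] = {}

    heading = math.radians(heading_deg)

    def synth(label: str, traj: Trajectory, duration: float):
        recs, truth, time = _synthesize_with_heading(
            label, traj, duration, mountings, error_model, rng, side, heading
        )
        for rec in recs.values():
            recset.add(label, rec)
        truth_orient[label] = truth
        return time

    for label, (traj, duration) in calibration_items(calibration_pose).items():
        synth(label, traj, duration)

    from .joint_angles import compute_joint_angles  # local import, no cycle

    for label, (traj, timing, hold) in tasks.items():
        time = synth(label, traj, timing.duration)
        truth_angles[label] = compute_joint_angles(
            truth_orient[label], side=side
        )
        target_windows[label] = hold

    return SyntheticScene(
        side=side,
        time=time if tasks else np.array([]),
        recordings=recset,
        mountings=dict(mountings),
        truth_orientations=truth_orient,
        truth_angles=truth_angles,
        target_windows=target_windows,
        error_model=error_model,
    )


def _synthesize_with_heading(
    label, traj, duration, mountings, error_model, rng, side, heading
):
    recs, truth, time = synthesize_item(
        label, traj, duration, mountings, error_model, rng, side
    )
    if heading:
        q_h = quat_from_axis_angle(_Z, heading)
        for seg, trace in truth.items():
            q_rot = quat_normalize(quat_multiply(np.tile(q_h, (trace.n_samples, 1)),
                                                 trace.quat))
            truth[seg] = OrientationTrace(trace.placement, trace.time, q_rot,
                                          trace.frame)
        # re-express the sensed streams: a global pre-rotation changes
        # neither gyro nor accel in the sensor frame when gravity stays
        # vertical and angular velocity rotates with the scene -- except
        # that it does change nothing at all: v_sensor = R_GS^T v_G and
        # both R_GS and v_G pick up the same left factor.  Recordings are
        # therefore reused unchanged.
    return recs, truth, time
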
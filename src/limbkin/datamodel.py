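"""Core domain types for distributed-IMU upper-limb kinematics.

The sensing chain carries eight IMUs: sternum, shoulder, upper arm and
forearm (the arm string) plus hand, thumb, index and middle finger (the
hand string).  Gyroscopes sample at 200 Hz and accelerometers at 100 Hz;
after ingestion the accelerometer stream is linearly interpolated onto the
gyroscope timebase, so in memory both streams share one set of timestamps.

Frame conventions
-----------------
* Anatomical segment frames have ``x`` along the segment's longitudinal
  direction.  At the neutral pose (arm hanging along the body, fingers
  extended) every segment frame is aligned with the body frame: ``x`` up,
  ``y`` medio-lateral (pointing right for a right-arm recording), ``z``
  anterior.
* The global frame has ``z`` vertical (up, from gravity), ``y`` horizontal
  along the hip-flexion rotation axis, ``x = y × z``.
* Joint angles are reported in degrees, zero at the neutral pose, positive
  for flexion/abduction and negative for extension/adduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import IncompleteCalibrationSetError, PlacementMismatchError
from .rotations import is_rotation_matrix

GYRO_RATE_HZ = 200.0
ACCEL_RATE_HZ = 100.0
GRAVITY = 9.81  # m/s^2

PLACEMENTS = (
    "sternum",
    "shoulder",
    "upper_arm",
    "forearm",
    "hand",
    "thumb",
    "index",
    "middle",
)

#: joint-angle channels, degrees, neutral pose = 0
CHANNELS = (
    "shoulder_flexion",
    "shoulder_abduction",
    "elbow_flexion",
    "forearm_supination",
    "wrist_flexion",
    "thumb_flexion",
    "index_flexion",
    "middle_flexion",
)

#: calibration / reference item labels used by the default protocol
NEUTRAL_ITEM = "neutral_pose"
HIP_FLEXION_ITEM = "hip_flexion"


@dataclass(frozen=True)
class SensorPlacement:
    """Mounting site of one IMU on the chain."""

    label: str
    side: str = "right"

    def __post_init__(self):
        if self.label not in PLACEMENTS:
            raise ValueError(f"unknown placement label {self.label!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class RawImuRecording:
    """Raw streams of one sensor for one labelled item or task.

    ``gyro`` (rad/s) and ``accel`` (m/s^2) are both sampled on the common
    gyroscope timebase ``time`` (seconds, strictly increasing); the native
    accelerometer rate is retained in ``accel_rate``.
    """

    placement: SensorPlacement
    time: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    gyro_rate: float = GYRO_RATE_HZ
    accel_rate: float = ACCEL_RATE_HZ

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = self.time.shape[0]
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("gyro and accel must be (N, 3) on the gyro timebase")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.isnan(self.gyro).any() or np.isnan(self.accel).any():
            raise ValueError("NaNs must be rejected at read time")

    @classmethod
    def from_streams(
        cls,
        placement: SensorPlacement,
        time_gyro: np.ndarray,
        gyro: np.ndarray,
        time_accel: np.ndarray,
        accel: np.ndarray,
        gyro_rate: float = GYRO_RATE_HZ,
        accel_rate: float = ACCEL_RATE_HZ,
    ) -> "RawImuRecording":
        """Build a recording from native-rate streams, upsampling the
        accelerometer onto the gyroscope timebase by linear interpolation."""
        time_gyro = np.asarray(time_gyro, dtype=float)
        accel_up = np.column_stack(
            [np.interp(time_gyro, time_accel, accel[:, k]) for k in range(3)]
        )
        return cls(placement, time_gyro, np.asarray(gyro, float), accel_up,
                   gyro_rate, accel_rate)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_samples > 1 else 0.0

    @property
    def fs(self) -> float:
        return self.gyro_rate


class LabelledRecordingSet:
    """Mapping ``item label -> {placement label -> RawImuRecording}``.

    Items are the calibration postures/movements (including the neutral
    pose and hip flexion used for the global frame) and the tasks
    (``task1`` .. ``task4``).
    """

    def __init__(self, items: Optional[Mapping[str, Mapping[str, RawImuRecording]]] = None):
        self.items: Dict[str, Dict[str, RawImuRecording]] = {
            k: dict(v) for k, v in (items or {}).items()
        }

    def add(self, item: str, recording: RawImuRecording) -> None:
        self.items.setdefault(item, {})[recording.placement.label] = recording

    def __getitem__(self, item: str) -> Dict[str, RawImuRecording]:
        return self.items[item]

    def __contains__(self, item: str) -> bool:
        return item in self.items

    def labels(self) -> List[str]:
        return sorted(self.items)

    def placements(self) -> List[str]:
        out = set()
        for recs in self.items.values():
            out.update(recs)
        return sorted(out, key=PLACEMENTS.index)

    def require(self, labels: Iterable[str]) -> None:
        missing = [lab for lab in labels if lab not in self.items]
        if missing:
            raise IncompleteCalibrationSetError(missing)


@dataclass
class SegmentCalibration:
    """Sensor-to-segment alignment for one IMU.

    ``s_R_seg`` holds the segment's anatomical axes as columns, expressed
    in the sensor frame; it maps segment-frame coordinates to sensor-frame
    coordinates and right-composes with the sensor orientation to give the
    segment orientation (``g_R_seg = g_R_s @ s_R_seg``).
    """

    placement: SensorPlacement
    s_R_seg: np.ndarray
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.s_R_seg = np.asarray(self.s_R_seg, dtype=float)
        if not is_rotation_matrix(self.s_R_seg, tol=1e-6):
            raise ValueError("s_R_seg is not a proper rotation matrix")


@dataclass
class GlobalFrameAlignment:
    """Per-sensor rotation taking each sensor's neutral-pose frame into the
    shared global frame (vertical from gravity, horizontal from hip flexion).

    ``rotations[label]`` is ``g_R_s`` at the neutral pose.
    ``gravity_spread_deg`` reports the maximum angular disagreement of the
    aligned gravity vectors across sensors.
    """

    rotations: Dict[str, np.ndarray]
    gravity_spread_deg: float = 0.0

    def __getitem__(self, label: str) -> np.ndarray:
        return self.rotations[label]


@dataclass
class OrientationTrace:
    """Unit-quaternion orientation time series of a sensor or segment in
    the global frame (scalar-first, Hamilton convention)."""

    placement: SensorPlacement
    time: np.ndarray
    quat: np.ndarray
    frame: str = "sensor_in_global"  # or "segment_in_global"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.quat.shape != (self.time.shape[0], 4):
            raise ValueError("quat must be (N, 4) matching timestamps")
        norms = np.linalg.norm(self.quat, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must be unit norm")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def check_placement(self, calib: SegmentCalibration) -> None:
        if calib.placement.label != self.placement.label:
            raise PlacementMismatchError(
                f"trace is from {self.placement.label!r}, calibration is for "
                f"{calib.placement.label!r}"
            )


class JointAngleTrace:
    """Named upper-limb joint angles over time, degrees, neutral pose = 0.

    Values lie in [-180, 180]; samples where an angle is undefined (the
    segment axis nearly normal to its projection plane) are NaN.
    """

    def __init__(self, time: np.ndarray, angles: Mapping[str, np.ndarray]):
        self.time = np.asarray(time, dtype=float)
        self.angles: Dict[str, np.ndarray] = {}
        for name, vals in angles.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.time.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.max() > 180.0 + 1e-9 or finite.min() < -180.0 - 1e-9):
                raise ValueError(f"channel {name!r} outside [-180, 180] deg")
            self.angles[name] = vals

    @property
    def channels(self) -> List[str]:
        return list(self.angles)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.angles[channel]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for name, vals in self.angles.items():
            df[name] = vals
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "JointAngleTrace":
        cols = [c for c in df.columns if c != "time_s"]
        return cls(df["time_s"].to_numpy(), {c: df[c].to_numpy() for c in cols})

    def crop(self, t0: float, t1: float) -> "JointAngleTrace":
        m = (self.time >= t0) & (self.time <= t1)
        return JointAngleTrace(self.time[m], {k: v[m] for k, v in self.angles.items()})
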
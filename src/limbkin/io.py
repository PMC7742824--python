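"""Readers and writers for raw recordings, calibrations and joint angles.

On-disk layout for raw data: one directory per labelled item (calibration
posture/movement or task), one CSV per sensor inside it::

    recordings/
      neutral_pose/
        sternum.csv  shoulder.csv  upper_arm.csv ...
      hip_flexion/
        ...
      task2/
        ...

Each CSV has columns ``time_s, gx, gy, gz, ax, ay, az``.  Two accelerometer
layouts are supported: ``interleaved`` (the native acquisition pattern —
gyro rows at 200 Hz with accelerometer columns populated on every other row
at 100 Hz, blank elsewhere) and ``dense`` (accelerometer pre-interpolated
onto every row).  Gyro units may be ``rad`` (rad/s) or ``deg`` (deg/s);
everything is converted to SI on read.  Rows containing NaNs are dropped
with a logged count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ACCEL_RATE_HZ,
    GYRO_RATE_HZ,
    GlobalFrameAlignment,
    JointAngleTrace,
    LabelledRecordingSet,
    RawImuRecording,
    SegmentCalibration,
    SensorPlacement,
)
from .errors import NonMonotoneTimestampsError

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["time_s", "gx", "gy", "gz", "ax", "ay", "az"]


@dataclass
class CsvDialect:
    """Configuration of the raw CSV flavour."""

    gyro_units: str = "rad"  # 'rad' (rad/s) or 'deg' (deg/s)
    accel_layout: str = "interleaved"  # or 'dense'
    side: str = "right"

    def __post_init__(self):
        if self.gyro_units not in ("rad", "deg"):
            raise ValueError("gyro_units must be 'rad' or 'deg'")
        if self.accel_layout not in ("interleaved", "dense"):
            raise ValueError("accel_layout must be 'interleaved' or 'dense'")


def read_sensor_csv(
    path: Path, placement: SensorPlacement, dialect: CsvDialect
) -> RawImuRecording:
    df = pd.read_csv(path)
    missing_cols = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    # in the interleaved layout blank accel cells are expected, not NaN rows
    accel_mask = df[["ax", "ay", "az"]].notna().all(axis=1)
    core = df[["time_s", "gx", "gy", "gz"]]
    bad = core.isna().any(axis=1) | (
        accel_mask ^ df[["ax", "ay", "az"]].notna().any(axis=1)
    )
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) containing NaNs", path, n_bad)
        df = df[~bad].reset_index(drop=True)
        accel_mask = df[["ax", "ay", "az"]].notna().all(axis=1)

    t = df["time_s"].to_numpy(float)
    if t.size > 1:
        step = np.diff(t)
        if np.any(step <= 0):
            row = int(np.argmax(step <= 0)) + 1
            raise NonMonotoneTimestampsError(row, path)

    gyro = df[["gx", "gy", "gz"]].to_numpy(float)
    if dialect.gyro_units == "deg":
        gyro = np.deg2rad(gyro)

    t_acc = t[accel_mask.to_numpy()]
    accel = df.loc[accel_mask, ["ax", "ay", "az"]].to_numpy(float)
    if t_acc.size == 0:
        raise ValueError(f"{path}: no accelerometer samples present")
    return RawImuRecording.from_streams(
        placement, t, gyro, t_acc, accel,
        gyro_rate=GYRO_RATE_HZ, accel_rate=ACCEL_RATE_HZ,
    )


def read_recording(
    path, dialect: Optional[CsvDialect] = None, required: Iterable[str] = ()
) -> LabelledRecordingSet:
    """Read a directory of labelled items into a validated recording set.

    ``required`` labels that are absent raise an incomplete-set error
    naming the missing items.
    """
    dialect = dialect or CsvDialect()
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"recording directory not found: {root}")
    recset = LabelledRecordingSet()
    for item_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for csv_path in sorted(item_dir.glob("*.csv")):
            placement = SensorPlacement(csv_path.stem, side=dialect.side)
            recset.add(item_dir.name, read_sensor_csv(csv_path, placement, dialect))
    recset.require(required)
    return recset


def write_recording(
    recset: LabelledRecordingSet, path, dialect: Optional[CsvDialect] = None
) -> None:
    """Write a recording set in the documented directory/CSV layout."""
    dialect = dialect or CsvDialect()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for item, sensors in recset.items.items():
        item_dir = root / item
        item_dir.mkdir(exist_ok=True)
        for label, rec in sensors.items():
            gyro = rec.gyro
            if dialect.gyro_units == "deg":
                gyro = np.rad2deg(gyro)
            df = pd.DataFrame(
                {
                    "time_s": rec.time,
                    "gx": gyro[:, 0],
                    "gy": gyro[:, 1],
                    "gz": gyro[:, 2],
                    "ax": rec.accel[:, 0],
                    "ay": rec.accel[:, 1],
                    "az": rec.accel[:, 2],
                }
            )
            if dialect.accel_layout == "interleaved":
                stride = max(int(round(rec.gyro_rate / rec.accel_rate)), 1)
                mask = np.ones(len(df), dtype=bool)
                mask[::stride] = False
                df.loc[mask, ["ax", "ay", "az"]] = np.nan
            df.to_csv(item_dir / f"{label}.csv", index=False, float_format="%.9f")


def write_joint_angles(trace: JointAngleTrace, path) -> None:
    """Persist a joint-angle trace as CSV (degrees, 6 decimal places)."""
    trace.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_joint_angles(path) -> JointAngleTrace:
    return JointAngleTrace.from_frame(pd.read_csv(path))


def write_calibrations(
    calibrations: Dict[str, SegmentCalibration],
    path,
    alignment: Optional[GlobalFrameAlignment] = None,
) -> None:
    """Serialize calibrations (and optionally the global-frame alignment)
    as JSON with row-major 3x3 matrices."""
    payload = {
        "calibrations": {
            label: {
                "side": cal.placement.side,
                "s_R_seg": np.asarray(cal.s_R_seg).tolist(),
                "provenance": cal.provenance,
            }
            for label, cal in calibrations.items()
        }
    }
    if alignment is not None:
        payload["global_frame"] = {
            "rotations": {k: np.asarray(v).tolist() for k, v in alignment.rotations.items()},
            "gravity_spread_deg": alignment.gravity_spread_deg,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibrations(path):
    """Inverse of :func:`write_calibrations`; returns
    ``(calibrations, alignment_or_None)``."""
    payload = json.loads(Path(path).read_text())
    calibrations = {
        label: SegmentCalibration(
            SensorPlacement(label, side=entry.get("side", "right")),
            np.asarray(entry["s_R_seg"], dtype=float),
            dict(entry.get("provenance", {})),
        )
        for label, entry in payload["calibrations"].items()
    }
    alignment = None
    if "global_frame" in payload:
        gf = payload["global_frame"]
        alignment = GlobalFrameAlignment(
            {k: np.asarray(v, dtype=float) for k, v in gf["rotations"].items()},
            float(gf.get("gravity_spread_deg", 0.0)),
        )
    return calibrations, alignment


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
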
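"""Exception hierarchy for the reconstruction pipeline."""


class LimbkinError(Exception):
    """Base class for all package errors."""


class IncompleteCalibrationSetError(LimbkinError):
    """A required calibration item is missing from the recording set."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "incomplete calibration set; missing items: "
            + ", ".join(self.missing)
        )


class NonMonotoneTimestampsError(LimbkinError):
    """Timestamps in a raw recording are not strictly increasing."""

    def __init__(self, row: int, path=None):
        self.row = row
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"non-monotone timestamp at row {row}{where}")


class DegenerateAxisError(LimbkinError):
    """Static axis estimate failed (median accel norm too small)."""


class NoMovementError(LimbkinError):
    """Dynamic axis estimate failed (peak angular rate below threshold)."""


class CollinearAxesError(LimbkinError):
    """The two measured calibration axes are too close to collinear."""

    def __init__(self, angle_deg: float):
        self.angle_deg = angle_deg
        super().__init__(
            f"collinear calibration axes (separation {angle_deg:.1f} deg)"
        )


class DegenerateHorizontalAxisError(LimbkinError):
    """Hip-flexion rotation axis is too close to the gravity vertical."""


class PlacementMismatchError(LimbkinError):
    """A calibration was applied to a trace from a different sensor."""


class ProjectionDegenerateError(LimbkinError):
    """A vector is (numerically) normal to its projection plane."""


class NoPlateauError(LimbkinError):
    """No qualifying target-position plateau found in a task repetition."""
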
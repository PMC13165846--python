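"""Exception hierarchy for the gait-analysis pipeline.

Each processing stage raises a specific subclass so that the pipeline driver
can attach stage-labelled diagnostics and decide whether a failure is fatal
for the trial or only excludes part of the output (e.g. one stride).
"""


class ImuGaitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ImuGaitError, ValueError):
    """Non-finite, malformed, or out-of-contract input."""


class InsufficientDataError(ImuGaitError):
    """Series too short or empty for the requested operation."""


class NotStaticError(ImuGaitError):
    """A segment assumed static failed the angular-rate variance test."""


class DegenerateCalibrationError(ImuGaitError):
    """Calibration input is rank-deficient (e.g. duplicated positions)."""


class DegenerateFitError(ImuGaitError):
    """Ellipsoid fit input is coplanar or otherwise degenerate."""


class UnstableNeutralError(ImuGaitError):
    """Static neutral capture did not converge to a stable orientation."""


class UnusableSampleError(ImuGaitError):
    """A measurement vector had zero norm and cannot be normalized."""


class DegenerateOrientationError(ImuGaitError):
    """Euler decomposition requested within the gimbal-lock guard band."""

    def __init__(self, message: str, sample_index: int | None = None):
        super().__init__(message)
        self.sample_index = sample_index


class InitializationIncompleteError(ImuGaitError):
    """Fewer than the required number of stable cycles for thresholds."""


class MissingZuptError(ImuGaitError):
    """A stance phase contained no quiet foot-flat interval."""


class InsufficientStridesError(ImuGaitError):
    """Fewer than two initial contacts on a side."""


class InsufficientCyclesError(ImuGaitError):
    """No stable gait cycle available for per-cycle statistics."""


class AlignmentFailureError(ImuGaitError):
    """Cross-correlation peak too low to trust the estimated lag."""


class MissingNodeError(ImuGaitError):
    """A required sensor placement is absent from the recording."""


class InfeasibleProfileError(ImuGaitError):
    """Synthetic gait profile is internally inconsistent."""
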
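"""Exception types raised by the estimation pipeline.

Every stage raises a typed error so the top-level pipeline (and the CLI)
can report which processing step rejected a recording.
"""


class FootclearError(Exception):
    """Base class for all package errors."""


class RecordingFormatError(FootclearError, ValueError):
    """A recording or calibration CSV is malformed (missing column,
    non-monotonic timestamps, non-uniform sampling)."""


class CalibrationError(FootclearError, RuntimeError):
    """Accelerometer calibration precondition failure or non-convergence."""


class StationaryDetectionError(FootclearError, RuntimeError):
    """No qualifying stationary window at the start of the recording."""


class SegmentationError(FootclearError, RuntimeError):
    """No foot-flat interval could be detected."""


class SynchronizationError(FootclearError, RuntimeError):
    """Peak-based alignment of two clearance traces failed (no peaks)."""


class PipelineStageError(FootclearError, RuntimeError):
    """Wraps an error raised inside :func:`footclear.clearance.estimate_clearance`
    with the name of the stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
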
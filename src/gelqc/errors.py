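"""Exception hierarchy.

All gelqc errors derive from :class:`GelQCError` so callers can catch one
type; the subclasses distinguish unusable inputs, invalid parameters, and
the two detection stages that support manual override when they fail.
"""


class GelQCError(Exception):
    """Base class for all gelqc errors."""


class InputError(GelQCError):
    """A file or external resource could not be read."""


class ValidationError(GelQCError):
    """A parameter or data structure violates its contract."""


class LaneDetectionError(GelQCError):
    """Automatic lane detection failed; supply boundaries manually."""


class CalibrationError(GelQCError):
    """Ladder marker localization or calibration failed."""


class StageError(GelQCError):
    """Wraps an error with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
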
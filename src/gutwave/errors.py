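"""Exception hierarchy for the gutwave pipeline.

All pipeline-specific failures derive from :class:`GutwaveError` so callers
can catch one base class; argument-validation failures additionally derive
from :class:`ValueError`.
"""


class GutwaveError(Exception):
    """Base class for all gutwave errors."""


class InvalidArgumentError(GutwaveError, ValueError):
    """An argument violated a documented precondition."""


class NoRhythmError(GutwaveError):
    """No rhythmic activity detectable where the operation requires one."""


class InsufficientEventsError(GutwaveError):
    """Fewer wave events than the operation needs (< 2)."""


class DegenerateGeometryError(GutwaveError):
    """Electrode geometry cannot support a plane-wave fit."""


class RejectedRecordingError(GutwaveError):
    """Recording failed the baseline signal-quality checks."""

    def __init__(self, reasons):
        self.reasons = list(reasons)
        super().__init__(f"recording rejected: {', '.join(self.reasons)}")


class DegenerateBaselineError(GutwaveError):
    """A unit-bearing baseline feature is zero; percentage change undefined."""


class DegenerateLabelsError(GutwaveError):
    """Only one class present where a binary contrast is required."""


class NoSignificantFeaturesError(GutwaveError):
    """The t-test screen selected no feature; model building aborts."""


class AlgorithmIncompatibleError(GutwaveError):
    """Algorithm cannot be applied to this dataset (e.g. missing features)."""
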
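"""Exception hierarchy for repertoire analysis failures.

Every error raised by this package derives from :class:`RepertoireError`,
so callers can catch one type at the pipeline boundary.
"""


class RepertoireError(Exception):
    """Base class for all package errors."""


class FormatError(RepertoireError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class ValidationError(RepertoireError):
    """Input values violate a precondition (negative counts, bad thresholds...)."""


class EmptySampleError(RepertoireError):
    """A clonotype table has zero total reads or no rows."""


class DepthError(RepertoireError):
    """Sample has fewer reads than the downsampling target (short_policy=error)."""


class ReferenceError_(RepertoireError):
    """Healthy-control reference cannot be built (too few individuals)."""


class PairingError(RepertoireError):
    """A subject lacks the samples needed to form a longitudinal pair."""


class EmptyCohortError(RepertoireError):
    """An event table has no subjects, or no events where some are required."""


class UndefinedStatisticError(RepertoireError):
    """A statistic is undefined for the given data (e.g. HR with no events)."""


class PipelineError(RepertoireError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
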
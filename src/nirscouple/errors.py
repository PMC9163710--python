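"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`NirsCoupleError`, so callers can distinguish domain failures
(bad inputs, degenerate data, numerically hopeless windows) from bugs.
"""


class NirsCoupleError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NirsCoupleError, ValueError):
    """An argument violates a documented precondition."""


class TooShortError(NirsCoupleError):
    """A series or valid span is too short for the requested analysis."""


class InsufficientOverlapError(NirsCoupleError):
    """Channels or valid spans do not overlap enough to proceed."""


class DegenerateInputError(NirsCoupleError):
    """Input data is degenerate (zero variance, non-positive denominator...)."""


class ArtifactSaturationError(NirsCoupleError):
    """Artifact detection flagged essentially the whole series."""


class NumericalConditioningError(NirsCoupleError):
    """A linear system in the inference is too ill-conditioned to solve."""


class FormatError(NirsCoupleError):
    """A data file does not match the expected on-disk format."""


class PipelineError(NirsCoupleError):
    """The end-to-end pipeline produced no usable subjects."""
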
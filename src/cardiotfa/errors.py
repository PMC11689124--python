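"""Exception hierarchy.

All input-contract violations raise :class:`ValidationError` subclasses so the
CLI can map them to a single exit code; numerical-fitting failures raise
:class:`ConvergenceError`.
"""


class CardioTFAError(Exception):
    """Base class for all package errors."""


class ValidationError(CardioTFAError, ValueError):
    """An input violated a documented precondition."""


class FlatTraceError(ValidationError):
    """A trace has (near-)zero variance; no pulses or breaths to detect."""


class TooFewBeatsError(ValidationError):
    """Fewer beats than spectral analysis requires."""


class MassArtifactError(ValidationError):
    """A majority of beats were flagged as artifacts; refusing silent mass correction."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input file."""


class NonMonotoneTimeError(ValidationError):
    """The time column is not strictly increasing."""


class NonUniformSamplingError(ValidationError):
    """Sample spacing deviates from a constant step beyond tolerance."""


class NonFiniteValueError(ValidationError):
    """A channel contains NaN or infinite values."""


class ConvergenceError(CardioTFAError, RuntimeError):
    """A model fit failed to converge."""
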
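"""Exception hierarchy for the stumpwave package."""


class StumpwaveError(Exception):
    """Base class for all package errors."""


class ValidationError(StumpwaveError, ValueError):
    """A domain object or parameter violates a documented invariant."""


class FormatError(StumpwaveError, ValueError):
    """A file does not conform to the documented plain-text dialect."""


class InsufficientBeatsError(StumpwaveError):
    """Fewer usable cardiac cycles than the configured minimum."""


class InsufficientConcordantBeatsError(InsufficientBeatsError):
    """Too few beats pass the correlation gate.

    Carries the per-beat correlation coefficients so the caller can inspect
    why the recording was rejected.
    """

    def __init__(self, message: str, correlations=None):
        super().__init__(message)
        self.correlations = correlations


class TauUndefinedError(StumpwaveError):
    """The diastolic segment does not support a decay-constant estimate."""
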
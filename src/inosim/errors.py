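"""Exception types shared across the pipeline."""


class InosimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(InosimError):
    """A model parameter violates its physical constraints."""


class SynthesisError(InosimError):
    """Trace synthesis received inconsistent biomarker anchors."""


class ExtractionError(InosimError):
    """A biomarker cannot be extracted from the given trace."""


class CalibrationError(InosimError):
    """Population calibration produced an empty accepted set."""

    def __init__(self, message, rejection_counts=None):
        super().__init__(message)
        self.rejection_counts = dict(rejection_counts or {})


class FitError(InosimError):
    """Dose-response fitting failed to converge."""


class SchemaError(InosimError):
    """An input table violates the expected schema."""
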
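"""Exception hierarchy.

Validation errors signal data that violates a contract (non-binary outcome,
missing cells); configuration errors signal a bad request against valid data
(unknown column names); fit errors carry diagnostics from a failed model fit
so the caller can decide a redraw policy.
"""


class PmstabilityError(Exception):
    """Base class for all package errors."""


class ValidationError(PmstabilityError, ValueError):
    """Input data violates a documented invariant."""


class ConfigurationError(PmstabilityError, ValueError):
    """The request does not match the data (e.g. unknown column names)."""


class FitError(PmstabilityError, RuntimeError):
    """A model fit failed; carries diagnostics for the caller's redraw policy."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateCurveError(PmstabilityError, ValueError):
    """A calibration curve cannot be estimated (constant risks or outcomes)."""


class InstabilityInfeasibleError(PmstabilityError, RuntimeError):
    """Bootstrap redraw cap exceeded; the data are too sparse for the procedure."""
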
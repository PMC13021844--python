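"""Exception hierarchy for the pharmits package."""


class PharmitsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PharmitsError):
    """A table or configuration violates the canonical schema."""


class GapError(ValidationError):
    """A monthly series is missing one or more calendar months."""


class OutOfWindowError(ValidationError):
    """A date falls outside the study window."""


class UndefinedMetricError(PharmitsError):
    """A utilization metric is undefined (e.g. zero population)."""


class MissingDataError(PharmitsError):
    """Required fields (e.g. incident counts) are absent."""


class InsufficientHistoryError(PharmitsError):
    """An incident-count request lacks the full 12-month lookback."""


class SelectionError(PharmitsError):
    """No candidate ARIMA order converged during model selection."""


class FitError(PharmitsError):
    """Maximum-likelihood estimation failed to converge."""


class DesignError(FitError):
    """The regression design is rank deficient after differencing."""


class InsufficientResidualsError(PharmitsError):
    """Residual vector too short for the requested diagnostic."""
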
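"""Exception hierarchy for ritopk.

All package errors derive from :class:`RitopkError` so callers can catch
everything the library raises with a single except clause.
"""


class RitopkError(Exception):
    """Base class for all ritopk errors."""


class FormatError(RitopkError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class ValidationError(RitopkError):
    """Row- or field-level data validation failed (negative time, duplicate records, ...)."""


class AnalyteLookupError(RitopkError, KeyError):
    """An analyte name could not be resolved in the analyte table."""


class ConfigurationError(RitopkError):
    """A required configuration value (e.g. molar mass) is unset or inconsistent."""


class UnitError(RitopkError):
    """Quantities with incompatible units were combined."""


class EmptyProfileError(RitopkError):
    """A profile has no quantifiable observations left."""


class InsufficientDataError(RitopkError):
    """Too few eligible observations for the requested estimate."""


class NoTerminalPhaseError(RitopkError):
    """The terminal log-linear regression has a non-negative slope."""


class ExtrapolationError(RitopkError):
    """A partial AUC interval lies outside the observed range and no lambda_z is available."""


class DomainError(RitopkError, ValueError):
    """An argument is outside its mathematical domain (non-positive value on log scale, ...)."""


class SampleSizeError(RitopkError):
    """Fewer observations/subjects than the statistical procedure requires."""


class PairingError(RitopkError):
    """Baseline and treated samples cannot be matched subject-by-subject."""


class DegenerateRegressionError(RitopkError):
    """Regression is undefined (zero variance in the predictor)."""


class IntegrationError(RitopkError):
    """The ODE solver failed or produced an invalid (negative) state."""


class SteadyStateError(RitopkError):
    """The run-in period did not reach steady state within tolerance."""


class ComparabilityError(RitopkError):
    """Two fit results are not comparable (different data)."""
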
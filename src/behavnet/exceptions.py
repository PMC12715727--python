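"""Exception hierarchy for behavnet.

Every anticipated failure mode raises a subclass of :class:`BehavnetError`
so callers can distinguish package errors from programming bugs.
"""


class BehavnetError(Exception):
    """Base class for all behavnet errors."""


class InvalidParametersError(BehavnetError):
    """Model parameters violate a structural invariant (e.g. asymmetric W)."""


class CapacityError(BehavnetError):
    """Problem size exceeds what exact enumeration supports."""


class UndefinedStatisticError(BehavnetError):
    """A statistic is undefined for the given inputs (e.g. zero marginal)."""


class CodingError(BehavnetError):
    """A raw survey response is outside its documented vocabulary."""


class InputValidationError(BehavnetError):
    """Input table or configuration fails structural validation."""


class GenerationError(BehavnetError):
    """Synthetic data generation hit a pathological configuration."""


class ConvergenceError(BehavnetError):
    """An iterative fit failed to converge."""

    def __init__(self, message, last_deviance=None):
        super().__init__(message)
        self.last_deviance = last_deviance


class SeparationError(BehavnetError):
    """Complete separation detected in a logistic regression term."""

    def __init__(self, message, term=None):
        super().__init__(message)
        self.term = term


class StabilityError(BehavnetError):
    """Too many bootstrap replicates failed to refit."""
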
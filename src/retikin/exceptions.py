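"""Exception hierarchy for retikin."""


class RetikinError(Exception):
    """Base class for all package errors."""


class ValidationError(RetikinError, ValueError):
    """Invalid user input (negative rate, hematocrit out of range, ...)."""


class DegenerateModelError(RetikinError):
    """Model structure admits no solution (singular balance system,
    zero denominator in the loss-partition constraint, ...)."""


class ModelStructureError(RetikinError):
    """Structural anomaly such as a first-return probability >= 1."""


class IntegrationError(RetikinError):
    """Tracer simulation failed to meet tolerance."""


class ConvergenceError(RetikinError):
    """Nonlinear fit failed to converge. Carries best-so-far parameters."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UnidentifiableParameterError(RetikinError):
    """Singular information matrix; names the offending parameters."""

    def __init__(self, message, parameters=()):
        super().__init__(message)
        self.parameters = tuple(parameters)


class ConfigurationError(RetikinError):
    """Infeasible or inconsistent run configuration."""
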
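"""Exception and warning types used across the package."""


class DimensionError(ValueError):
    """A point, grid or observation has the wrong dimension."""


class DomainError(ValueError):
    """A point lies outside the declared domain of a vector field or density."""


class NumericalError(ArithmeticError):
    """A computed quantity (divergence, density) is non-finite."""


class CapabilityError(RuntimeError):
    """An operation was requested that the object does not support
    (e.g. sampling a density defined only through its log-density,
    or quadrature on a field without an attached uniform grid)."""


class SolverError(RuntimeError):
    """ODE integration failed.  ``last_time`` holds the last time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class EstimationError(RuntimeError):
    """Likelihood or maximum-likelihood computation could not be completed."""


class ConfigError(ValueError):
    """Invalid run configuration.  ``path`` names the offending field."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path


class ConditioningWarning(UserWarning):
    """The backward-forward round trip exceeded its tolerance; the
    backward solution is ill-conditioned (e.g. chaotic or strongly
    contracting dynamics)."""


class FlatProfileWarning(UserWarning):
    """All finite values of a likelihood profile are (numerically) equal;
    the reported maximizer is only a tie-breaking convention."""
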
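"""Exception hierarchy shared across the package."""


class DynapredError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DynapredError):
    """Invalid simulation or protocol configuration."""


class SchemaError(DynapredError):
    """Malformed cohort/prediction files."""


class NoEventsError(DynapredError):
    """A model fit was requested on a risk set containing no events."""


class ConvergenceError(DynapredError):
    """Partial-likelihood maximization failed to converge.

    Parameters
    ----------
    message : str
    covariate : str, optional
        Name of the covariate implicated (e.g. under monotone likelihood).
    """

    def __init__(self, message: str, covariate: str | None = None):
        super().__init__(message)
        self.covariate = covariate


class UndefinedMetricError(DynapredError):
    """An accuracy metric is undefined on the supplied data (e.g. no cases)."""


class EmptyRiskSetError(DynapredError):
    """No subjects remain at risk at the requested landmark time."""
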
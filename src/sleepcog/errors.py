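"""Exception types shared across the package."""


class SleepcogError(Exception):
    """Base class for package errors."""


class ConfigurationError(SleepcogError):
    """Invalid simulation or pipeline configuration."""


class ConvergenceError(SleepcogError):
    """Iterative fit failed to converge.

    Carries the optimizer iteration trace in ``trace`` when available.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RankDeficiencyError(SleepcogError):
    """Design or confound matrix is rank deficient.

    ``columns`` names the aliased (collinear) columns.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class SchemaError(SleepcogError):
    """An input table violates the expected schema."""
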
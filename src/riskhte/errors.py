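"""Exception hierarchy.

Every error the pipeline can raise derives from :class:`RiskHTEError`, so
callers (and the CLI) can distinguish validation failures (exit code 2) from
numerical failures (exit code 3).
"""


class RiskHTEError(Exception):
    """Base class for all riskhte errors."""


class ConfigurationError(RiskHTEError):
    """Invalid synthetic-trial or analysis configuration."""


class SchemaError(RiskHTEError):
    """Variable schema is inconsistent or a required column is absent."""


class ValidationError(RiskHTEError):
    """Data values violate the declared schema (e.g. unknown category level)."""


class InputError(RiskHTEError):
    """Unreadable or empty input file."""


class ArgumentError(RiskHTEError):
    """Invalid argument to an operation (unknown variable, bad rate, ...)."""


class DegenerateDesignError(RiskHTEError):
    """Design matrix is rank-deficient / a variable has a single observed level."""


class ConvergenceError(RiskHTEError):
    """Iterative fit failed to converge within the iteration cap.

    Carries the last coefficient iterate in ``last_params``.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class SeparationError(RiskHTEError):
    """(Quasi-)complete separation detected during a logistic fit."""


class UndefinedMetricError(RiskHTEError):
    """Performance metric undefined (e.g. single-class outcome)."""


class StratificationError(RiskHTEError):
    """Too few observations to form the requested number of strata."""


class DegenerateStrataError(StratificationError):
    """Quantile strata degenerate because of heavy ties."""


class UndefinedEstimateError(RiskHTEError):
    """Effect estimate undefined (e.g. empty arm)."""
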
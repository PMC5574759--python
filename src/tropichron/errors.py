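"""Exception hierarchy for the pipeline."""


class TropichronError(Exception):
    """Base class for all package errors."""


class ConfigError(TropichronError):
    """Invalid simulation or run configuration."""


class FormatError(TropichronError):
    """Malformed input file; message carries the file position."""


class SchemaError(FormatError):
    """A required column is missing or has the wrong type."""


class OrderError(FormatError):
    """Records are not in the required sort order."""


class OverflowError_(TropichronError):
    """A value cannot be represented in the target format."""


class DomainError(TropichronError):
    """An argument lies outside the mathematical domain of an operation."""


class SeriesTooShortError(TropichronError):
    """A series is shorter than an operation's minimum length."""


class EmptyChronologyError(TropichronError):
    """No year satisfies the minimum sample depth."""


class UndefinedStatisticError(TropichronError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class SelectionError(TropichronError):
    """A requested ring position does not exist."""


class InfeasibleAssignmentError(TropichronError):
    """No monotone calendar-year assignment exists for a tree's samples."""


class StageError(TropichronError):
    """A pipeline stage failed or its inputs are missing."""


class ConvergenceError(TropichronError):
    """Numerical optimization failed to converge.

    Carries the best parameters found so far in ``best_params`` and the
    gradient norm at that point in ``grad_norm``.
    """

    def __init__(self, message, best_params=None, grad_norm=None):
        super().__init__(message)
        self.best_params = best_params
        self.grad_norm = grad_norm
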
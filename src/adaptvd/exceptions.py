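"""Exception hierarchy for adaptvd."""


class AdaptvdError(Exception):
    """Base class for all package errors."""


class ValidationError(AdaptvdError):
    """Invalid parameter values, masks, or structural declarations."""


class DomainError(AdaptvdError):
    """Argument outside the mathematical domain of an operation."""


class UnsupportedKindError(AdaptvdError):
    """Operation not defined for this expansion-function kind."""


class SolverError(AdaptvdError):
    """ODE integration failed or produced non-finite state."""


class PredictionError(AdaptvdError):
    """A model prediction is non-positive at an observation record."""


class FitFailureError(AdaptvdError):
    """All optimization starts failed to converge."""


class UndefinedStatisticError(AdaptvdError):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""


class EmptyDatasetError(AdaptvdError):
    """An operation produced or received a dataset with no observations."""


class ParseError(AdaptvdError):
    """A tabular input file violates the expected column contract."""
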
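"""Exception hierarchy shared by all strucdiv modules."""


class StrucdivError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StrucdivError):
    """A domain-type invariant was violated."""


class SchemaError(StrucdivError):
    """An input table is missing a required column."""


class RowError(StrucdivError):
    """A table row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(StrucdivError):
    """A sequence file does not have the expected structure."""


class UndefinedMetricError(StrucdivError):
    """A divergence metric is undefined for this input (e.g. no aligned columns)."""


class IdentifiabilityError(StrucdivError):
    """Too few distinct design points to identify the model parameters."""


class FitError(StrucdivError):
    """An optimizer failed to converge."""


class InvalidModelError(StrucdivError):
    """A fitted model violates its validity constraints (e.g. f(1) <= 0)."""


class DegenerateDataError(StrucdivError):
    """A regression input has zero variance or is perfectly collinear."""


class InsufficientDataError(StrucdivError):
    """Not enough records remain after filtering to fit the models."""


class GenerationError(StrucdivError):
    """A synthetic-data request is unsatisfiable."""


class ConfigurationError(StrucdivError):
    """A pipeline configuration is incomplete or inconsistent."""
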
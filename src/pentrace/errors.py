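"""Exception hierarchy shared by all pentrace modules."""


class PentraceError(Exception):
    """Base class for all pentrace errors."""


class ParseError(PentraceError):
    """A recording file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(PentraceError):
    """A recording or configuration violates a structural invariant."""


class DegenerateInputError(PentraceError):
    """An operation received an input too small to be meaningful (e.g. empty vector)."""


class EmptyMovementError(PentraceError):
    """A recording has no segment of the requested movement type."""


class MissingTaskError(PentraceError):
    """A session lacks one of the template tasks required for merging."""


class SchemaError(PentraceError):
    """Column names of a feature matrix do not match the expected schema."""


class UndefinedMetricError(PentraceError):
    """A classification metric has a zero denominator."""


class StratificationError(PentraceError):
    """A class has too few members for the requested number of CV folds."""
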
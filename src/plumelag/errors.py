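"""Exception hierarchy shared across the package."""


class PlumelagError(Exception):
    """Base class for package errors."""


class FormatError(PlumelagError, ValueError):
    """A file does not conform to the documented dialect (missing column,
    duplicated date, truncated audio header, ...)."""


class RowParseError(FormatError):
    """A single row failed to parse; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ValidationError(PlumelagError, ValueError):
    """A configuration or parameter value violates its invariant."""


class ParameterError(ValidationError):
    """A simulation or analysis parameter is out of range."""


class InsufficientDataError(PlumelagError, ValueError):
    """Not enough data to run the requested operation (e.g. a decomposition
    over fewer than two periods)."""


class DegenerateDataError(PlumelagError, ValueError):
    """Input is degenerate for the requested statistic (e.g. a constant
    series has no defined autocorrelation)."""
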
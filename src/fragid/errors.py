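"""Exception hierarchy shared across the pipeline."""


class FragidError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FragidError, ValueError):
    """A parameter violates its documented domain."""


class InvalidInputError(FragidError, ValueError):
    """An input object (sequence, table, ...) is unusable."""


class EmptyInputError(InvalidInputError):
    """An operation received an empty collection it cannot act on."""


class AlphabetError(InvalidInputError):
    """A sequence contains a character outside the protein alphabet."""


class ParseError(FragidError, ValueError):
    """A file could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyConsensusError(FragidError):
    """All alignment columns were gap-dominated; no consensus exists."""


class EmptyModelError(FragidError):
    """Profile construction found no usable match columns."""


class NoDataError(FragidError):
    """Aggregation was asked for but every score is missing."""
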
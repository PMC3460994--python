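"""Exception hierarchy shared across the package."""


class HicproxError(Exception):
    """Base class for all package errors."""


class ParseError(HicproxError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(HicproxError):
    """Input parsed but violates a contract (coordinates, overlaps, ranges)."""


class LookupError_(HicproxError):
    """A named entity (band, chromosome) was not found."""


class UndefinedScoreError(HicproxError):
    """A score is undefined (no usable bins); distinct from a zero score."""


class DrawFailureError(HicproxError):
    """A permutation draw could not satisfy its constraints."""


class NoSignalError(HicproxError):
    """A contact-map query found no reads to operate on."""
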
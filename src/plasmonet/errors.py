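"""Exception hierarchy.

``ArgumentError`` signals a caller mistake (bad parameter value),
``DataError`` signals a problem with the data themselves (missing
replicates, non-positive abundances, ragged tables).  The CLI maps
``DataError`` to exit code 3 and usage problems to exit code 2.
"""


class PlasmonetError(Exception):
    """Base class for all package errors."""


class ArgumentError(PlasmonetError, ValueError):
    """A parameter value violates a precondition."""


class DataError(PlasmonetError):
    """Input data violate a structural or value constraint."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
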
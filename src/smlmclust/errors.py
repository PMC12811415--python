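"""Exception hierarchy shared across the package.

Each class maps to one of the CLI's categorized exit codes.
"""


class SmlmclustError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SmlmclustError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class FormatError(SmlmclustError):
    """A file does not conform to the expected dialect (e.g. missing column)."""

    exit_code = 3


class RowParseError(FormatError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class EmptyTableError(FormatError):
    """The file contains no rows at all (not even a header)."""


class ArgumentError(SmlmclustError, ValueError):
    """An operation received an out-of-domain argument."""

    exit_code = 4


class IOFailure(SmlmclustError):
    """Filesystem-level failure (unwritable path, missing file)."""

    exit_code = 5
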
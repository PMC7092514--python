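"""Exception hierarchy shared across the package.

Each error class maps to a distinct nonzero CLI exit code (see cli.py).
"""


class SplicescapeError(Exception):
    """Base class for all package errors."""


class ConfigError(SplicescapeError):
    """Configuration file missing, unreadable, or schema-violating."""


class InputError(SplicescapeError):
    """A required input file is missing or unreadable."""


class GffParseError(SplicescapeError):
    """Malformed annotation line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(SplicescapeError):
    """Structurally parseable input that violates a model invariant."""


class TableParseError(SplicescapeError):
    """Malformed tabular input (PSI/TPM/association tables)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
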
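"""Exception hierarchy shared across the package.

``ValidationError`` covers bad data (exit code 1 in the CLI); plain
``OSError`` covers I/O problems (exit code 2).
"""


class TwinPafError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TwinPafError, ValueError):
    """Input data violates a documented invariant."""


class TableFormatError(ValidationError):
    """A delimited input file does not conform to the expected schema."""


class UndefinedStatisticError(ValidationError):
    """A statistic is undefined for the given counts (e.g. no affected twins)."""


class LinkageError(ValidationError):
    """A mortality record cannot be matched to exactly one concordance estimate."""
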
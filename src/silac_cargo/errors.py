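"""Exception hierarchy shared across the package."""


class SilacCargoError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SilacCargoError):
    """A file does not conform to the expected format (missing column, bad FASTA, ...)."""


class DataError(SilacCargoError):
    """A file parses but its content violates an invariant (duplicate accession, ratio <= 0)."""


class UsageError(SilacCargoError):
    """An operation was called with inconsistent arguments (replicate mismatch, too few tables)."""


class DomainError(SilacCargoError, ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""


class DegenerateInputError(SilacCargoError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class ConfigError(SilacCargoError):
    """A simulation or pattern configuration failed validation."""
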
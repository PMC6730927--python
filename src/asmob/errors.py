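"""Exception hierarchy.

ConfigError and DataError map onto the CLI's exit codes (2 and 3).
"""


class AsmobError(Exception):
    """Base class for all package errors."""


class ConfigError(AsmobError):
    """Invalid configuration or parameter value."""


class DataError(AsmobError):
    """Malformed or inconsistent input data."""


class FastaError(DataError):
    pass


class SamError(DataError):
    pass


class TableError(DataError):
    pass


class CladeError(DataError):
    """Raised when reference clades cannot be recovered from the tree."""


class ReplicationError(DataError):
    """Raised when a MAG cannot support a coverage-slope estimate."""
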
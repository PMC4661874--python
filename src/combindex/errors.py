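"""Exception hierarchy shared across the pipeline.

Two broad families matter to callers: format errors (malformed input
files, exit code 2 from the CLI) and analysis/data errors (exit code 3).
"""


class CombindexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CombindexError):
    """Invalid run configuration (unknown agent, bad design, missing seed)."""


class DataError(CombindexError):
    """Input data violates an analysis precondition (bad control, unit mismatch)."""


class UnitMismatchError(DataError):
    """Arithmetic attempted between concentrations with different units."""


class InsufficientDataError(DataError):
    """Too few doses, replicates or animals for the requested operation."""


class FormatError(CombindexError):
    """Malformed input file (missing column, empty file)."""


class DomainError(CombindexError, ValueError):
    """Argument outside the mathematical domain of an operation."""
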
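"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`CellshiftError` so
callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class CellshiftError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CellshiftError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(CellshiftError):
    """Parsed data is internally inconsistent (dimensions, duplicates)."""


class ValidationError(CellshiftError):
    """An in-memory object or parameter violates its invariants."""


class EmptyResultError(CellshiftError):
    """A filtering step removed every cell; carries the offending step."""

    def __init__(self, step: str, message: str | None = None):
        self.step = step
        super().__init__(message or f"all cells removed at step {step!r}")


class ClusterTooSmallError(CellshiftError):
    """A group does not meet the minimum size for the subsampling scheme."""


class NumericalError(CellshiftError):
    """A numerical operation failed (singular matrix, infeasible rank)."""
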
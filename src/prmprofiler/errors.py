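"""Exception hierarchy shared across the package."""


class PrmProfilerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrmProfilerError):
    """A file or table does not conform to the expected format."""


class RecordError(PrmProfilerError):
    """A single record (row) is invalid; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class UnsupportedPatternError(PrmProfilerError):
    """A motif pattern uses a regex construct outside the per-position grammar."""


class InsufficientDataError(PrmProfilerError):
    """Too few peptides to build an alignment or profile."""
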
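"""Exception hierarchy for rankdist."""


class RankDistError(Exception):
    """Base class for all rankdist errors."""


class DuplicateMarkerError(RankDistError):
    """A marker name occurs more than once where uniqueness is required."""


class DimensionError(RankDistError):
    """A matrix or vector has an incompatible or odd dimension."""


class InvalidGenomeError(RankDistError):
    """A genome (or its vector/matrix encoding) violates the genome axioms."""


class UniverseMismatchError(RankDistError):
    """Two genomes that must share a marker universe do not."""


class InvalidOperationError(RankDistError):
    """An operation payload is internally inconsistent."""


class NotApplicableError(RankDistError):
    """An operation is not applicable to the given genome."""


class DuplicateLabelError(RankDistError):
    """Duplicate genome or taxon labels."""


class InvalidMatrixError(RankDistError):
    """A distance matrix is not symmetric/valid."""


class LeafSetError(RankDistError):
    """Two trees under comparison do not share the same leaf set."""


class ParameterError(RankDistError):
    """Invalid simulation or algorithm parameter."""


class UnsupportedError(RankDistError):
    """Requested feature is deliberately unsupported (e.g. duplications)."""


class ParseError(RankDistError):
    """Malformed input file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
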
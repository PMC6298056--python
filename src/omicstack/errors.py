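"""Exception hierarchy.

Every failure mode raised on purpose derives from :class:`OmicStackError`
so callers can catch package errors without catching programming bugs.
"""


class OmicStackError(Exception):
    """Base class for all package-level errors."""


class IdentifierError(OmicStackError):
    """Duplicate or malformed sample/feature identifiers."""


class ParseError(OmicStackError):
    """Non-numeric, non-missing cell encountered while reading a matrix."""


class ValidationError(OmicStackError):
    """A table, spec or configuration violates its invariants."""


class AlignmentError(OmicStackError):
    """Datasets and metadata cannot be reconciled onto a common sample set."""


class DegenerateDataError(OmicStackError):
    """Data carry no usable variance (e.g. all-constant columns)."""


class ImputationError(OmicStackError):
    """Missing-value interpolation cannot proceed (e.g. fully missing feature)."""


class SchemaError(OmicStackError):
    """Feature identifiers of new data do not match a fitted model."""


class InsufficientDataError(OmicStackError):
    """Too few subjects/samples/points for the requested operation."""


class SynchronizationError(OmicStackError):
    """Cross-validation folds disagree between stacking layers."""


class ApplicationError(OmicStackError):
    """A fitted model cannot be applied to the requested samples."""


class NetworkError(OmicStackError):
    """Correlation network cannot be built (e.g. all correlations degenerate)."""


class StageError(OmicStackError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
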
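"""Exception hierarchy used across the package."""


class SigTargetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SigTargetError):
    """A file could not be parsed; message names the offending line/cell."""


class DimensionError(ParseError):
    """Declared and actual matrix dimensions disagree."""


class DuplicateIdError(ParseError):
    """Gene or sample identifiers are not unique."""


class MetadataError(SigTargetError):
    """Sample metadata violates its invariants."""


class EmptyNetworkError(SigTargetError):
    """An interaction network file contained no usable edges."""


class UnknownDrugError(SigTargetError):
    """A drug identifier is absent from the sample metadata."""


class MissingDataError(SigTargetError):
    """A required signature / feature is unavailable for a (drug, gene, cell)."""


class MissingControlError(MissingDataError):
    """No control samples exist for a requested cell line."""


class ZeroVarianceError(SigTargetError):
    """Correlation requested on a constant vector; refusing to emit NaN."""


class SchemaError(SigTargetError):
    """Feature rows do not match the schema a trained model expects."""


class TrainingError(SigTargetError):
    """Model training preconditions are not met."""
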
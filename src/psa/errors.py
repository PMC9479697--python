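"""Exception types shared across the package."""


class PsaError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PsaError, ValueError):
    """Input data violates a precondition (length, emptiness, shape)."""


class InvalidParameterError(PsaError, ValueError):
    """A parameter value is outside its admissible range."""


class InsufficientDataError(PsaError, ValueError):
    """Recording too short for the requested windowing."""


class DegenerateInputError(PsaError, ValueError):
    """Input is degenerate for the estimator (e.g. zero variance)."""


class FormatError(PsaError, ValueError):
    """A file does not conform to the expected on-disk format."""


class SchemaError(PsaError, ValueError):
    """A structured input is missing a required channel/band/field."""


class ShapeError(PsaError, ValueError):
    """Array dimensions do not match the model configuration."""


class InvalidDistributionError(PsaError, ValueError):
    """A probability vector does not sum to one."""


class InvalidStateError(PsaError, RuntimeError):
    """Operation called in a state where it is not defined."""


class DegenerateLabelsError(PsaError, ValueError):
    """Label vector has fewer than two classes."""
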
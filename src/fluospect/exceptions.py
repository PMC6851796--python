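"""Exception hierarchy for the fluospect pipeline."""


class FluospectError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(FluospectError, ValueError):
    """A numeric or enum parameter is outside its documented domain."""


class GeometryError(FluospectError, ValueError):
    """Phantom geometry constraint violated (e.g. lesion outside liver)."""


class ShapeError(FluospectError, ValueError):
    """Arrays expected on a common grid have mismatching shapes."""


class InvalidInputError(FluospectError, ValueError):
    """Input array violates a physical precondition (e.g. negative activity)."""


class UndefinedComError(FluospectError, ArithmeticError):
    """Center of mass requested on an all-zero strip."""


class ExtractionFailureError(FluospectError, RuntimeError):
    """No respiratory peaks could be found; caller may fall back to
    uncompensated reconstruction."""


class DegenerateSignalError(FluospectError, RuntimeError):
    """Upper and lower envelopes coincide; normalization undefined."""


class EmptyBinError(FluospectError, RuntimeError):
    """A motion bin contains no frames; caller drops the bin."""


class InsufficientGateError(FluospectError, RuntimeError):
    """Gating accepted too few projections for reconstruction."""


class InvalidMaskError(FluospectError, ValueError):
    """A metric mask is empty or inconsistent."""


class UndefinedMetricError(FluospectError, ArithmeticError):
    """Metric denominator is non-positive."""


class AggregationError(FluospectError, ValueError):
    """Realization reports with mismatching experiment descriptors."""


class ConfigurationError(FluospectError, ValueError):
    """Pipeline configuration inconsistent (e.g. missing MVF bin field)."""
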
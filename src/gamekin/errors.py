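"""Exception hierarchy shared across the package."""


class GamekinError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GamekinError):
    """A trial file could not be parsed (carries line/record context)."""


class SchemaError(GamekinError):
    """A parsed record violates the trial schema (carries a field path)."""


class InsufficientDataError(GamekinError):
    """Too few samples / pointers / strokes to compute the requested metric."""


class ParameterError(GamekinError):
    """An invalid analysis parameter (nonpositive penalty, zero brush, ...)."""


class DegenerateGeometryError(GamekinError):
    """Degenerate geometric input: coincident line endpoints, <2 polyline vertices."""


class InfeasibleSegmentationError(GamekinError):
    """The signal is too short for K+1 segments of the minimum length."""


class ConstantSignalError(GamekinError):
    """A constant signal where variation is required (bandwidth, phase)."""


class UndefinedPhaseError(ConstantSignalError):
    """Instantaneous phase requested for a signal with no oscillation."""


class AlignmentError(GamekinError):
    """Series that must share a time grid have mismatched lengths."""


class EventPairingError(GamekinError):
    """Touch down/up events could not be paired into press intervals."""
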
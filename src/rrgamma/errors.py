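"""Typed exception hierarchy.

Every contract violation raises a subclass of :class:`RRGammaError`, so callers
(and the CLI exit-code mapping) can distinguish bad input from degenerate
mathematics from perturbation-model failures.
"""


class RRGammaError(Exception):
    """Base class for all package errors."""


class InvalidBeatOrder(RRGammaError):
    """Beat occurrence times are not strictly increasing (or not finite)."""


class InsufficientData(RRGammaError):
    """Too few beats/samples for the requested operation."""


class ZeroTimeStep(RRGammaError):
    """Duplicate timestamps make a finite difference undefined."""


class DegenerateGroups(RRGammaError):
    """Both groups collapse to the same point with zero extent."""


class InsufficientGroups(RRGammaError):
    """Fewer than two groups supplied to a between-group metric."""


class PerturbationCollision(RRGammaError):
    """Timing jitter produced a non-positive inter-beat interval."""


class EligibilityExhausted(RRGammaError):
    """No gap wide enough remains for an ectopic-beat insertion.

    Carries ``applied``, the number of insertions that succeeded before
    exhaustion, so callers can report partial progress.
    """

    def __init__(self, message: str, applied: int = 0):
        super().__init__(message)
        self.applied = applied


class StratificationError(RRGammaError):
    """A train/validation split left one class empty."""


class ParseError(RRGammaError):
    """Malformed input file; message names the offending line/row."""
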
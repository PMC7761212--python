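"""Exceptions and warning categories shared across the package."""

from __future__ import annotations


class HemequilError(Exception):
    """Base class for all analysis errors raised by this package."""


class ParseError(HemequilError):
    """A data file could not be parsed; the message names the offending line."""


class InsufficientDataError(HemequilError):
    """Fewer points than the operation's minimum."""


class TruncatedPeakError(HemequilError):
    """Chromatogram maximum sits at a trace boundary; no complete peak."""


class MultiPeakError(HemequilError):
    """More than one region of the trace rises above half-maximum."""


class NoTransitionError(HemequilError):
    """Thermal melt fit found no credible unfolding transition."""


class NoAssociationError(HemequilError):
    """All equilibrium points are effectively monomeric; Kd is undefined.

    This is the expected outcome for a monomer-only species such as AHb2,
    whose elution volume does not move with concentration.
    """


class FitConvergenceError(HemequilError):
    """A nonlinear fit failed to converge.

    ``fallback`` carries a cruder estimate (e.g. the Manning line estimate
    when the hyperbolic fit diverges) when one is available.
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class HemequilWarning(UserWarning):
    """Base category for analysis warnings (clipping, exclusions, range)."""
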
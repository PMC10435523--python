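"""Exception hierarchy.

Configuration errors mean the caller supplied invalid parameters;
data errors mean the signal/table content is unusable. Beat-level
conditions (no beats, degenerate morphology, indeterminate delay)
get their own types so pipelines can drop a window and keep going.
"""


class PiezoBPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PiezoBPError, ValueError):
    """Invalid parameter or spec object."""


class DataError(PiezoBPError, ValueError):
    """Input data violates a precondition (wrong shape, non-finite, ...)."""


class NoBeatsDetected(DataError):
    """A window contains no detectable pulse feet."""


class DegenerateBeat(DataError):
    """A beat lacks the fiducial structure needed for features."""


class IndeterminateDelay(DataError):
    """Inter-channel delay cannot be resolved (flat correlation, zero lag)."""


class PhaseLimit(PiezoBPError, RuntimeError):
    """Pump inflation requested beyond the maximum phase count."""
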
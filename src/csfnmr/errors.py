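"""Exception hierarchy for the csfnmr pipeline."""


class CsfNmrError(Exception):
    """Base class for all csfnmr errors."""


class InvalidParameterError(CsfNmrError, ValueError):
    """A numeric parameter is outside its admissible range."""


class ValidationError(CsfNmrError, ValueError):
    """An input object violates a structural contract."""


class NoPeakError(CsfNmrError):
    """No peak rises above the local baseline in the search window."""


class WindowTooNarrowError(CsfNmrError):
    """A half-maximum crossing falls outside the search window."""


class InsufficientCohortError(ValidationError):
    """Too few samples for a cohort-level computation."""


class DegenerateSampleError(ValidationError):
    """A sample row is degenerate (e.g. non-positive total area)."""


class OutOfRangeBinError(ValidationError):
    """A bin lies outside the spectral axis."""


class RankExhaustedError(CsfNmrError):
    """The data matrix ran out of rank before the requested components."""


class StratificationError(ValidationError):
    """A class is too rare for the requested stratified fold count."""


class DegenerateScoresError(CsfNmrError):
    """Score covariance is singular; the confidence ellipse is undefined."""
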
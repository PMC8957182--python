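"""Exception hierarchy.

Every anticipated failure mode raises a dedicated subclass of
:class:`SeptostrainError` so callers (and the pipeline's per-loop error
recorder) can distinguish bad inputs from genuine bugs.
"""


class SeptostrainError(Exception):
    """Base class for all package-specific errors."""


class InvalidPatternError(SeptostrainError):
    """Strain-pattern parameters contradict the pattern family."""


class InfeasiblePatternError(SeptostrainError):
    """Strain-pattern targets cannot be realized by any curve."""


class OutOfFieldError(SeptostrainError):
    """Ground-truth mesh trajectory leaves the image bounds."""


class SegmentationError(SeptostrainError):
    """Septal segmentation polygon is degenerate or unusable."""


class TrackingFailureError(SeptostrainError):
    """All mesh points lost in at least one frame pair."""


class StrainUndefinedError(SeptostrainError):
    """Too many invalid mesh points to define an average strain."""


class WindowTooShortError(SeptostrainError):
    """Systolic window contains fewer than three samples."""


class UndefinedSDIError(SeptostrainError):
    """SDI requested with zero systolic shortening."""


class InsufficientReferenceError(SeptostrainError):
    """Phase-duration reference table has too few rows."""


class TimingInfeasibleError(SeptostrainError):
    """Scaled valve timing does not fit inside the cardiac cycle."""


class InsufficientDataError(SeptostrainError):
    """Fewer paired measurements than the statistic requires."""


class MissingDataError(SeptostrainError):
    """Incomplete subjects-by-raters matrix (no imputation is done)."""


class DegenerateVarianceError(SeptostrainError):
    """Variance structure leaves the statistic undefined."""


class UndefinedCorrelationError(SeptostrainError):
    """Correlation of a zero-variance signal."""


class UndefinedKappaError(SeptostrainError):
    """Chance agreement is exactly 1; kappa is undefined."""


class UndefinedTestError(SeptostrainError):
    """Paired t-test with zero-variance differences."""


class ExtrapolationWarning(UserWarning):
    """Heart rate outside the fitted reference range; value clamped."""
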
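"""Labelled exception hierarchy.

Validation errors (malformed input files, bad configuration, precondition
violations on user-supplied data) map to CLI exit code 2; analysis errors
(a detector or statistical routine that cannot produce a result on otherwise
well-formed input) map to exit code 3.
"""


class Gait5mError(Exception):
    """Base class for all package errors."""


class ValidationError(Gait5mError):
    """Malformed input, bad configuration, or a violated precondition."""


class AnalysisError(Gait5mError):
    """A computation that cannot produce a result on valid input."""


class NotStaticError(AnalysisError):
    """Subject not static inside a window that must be quiet standing."""


class NoMovementError(AnalysisError):
    """No movement detected (velocity thresholds never crossed)."""


class SegmentationError(AnalysisError):
    """Step-event detection or phase construction failed."""


class FeatureError(AnalysisError):
    """Feature extraction failed (interval outside trace, no steps, ...)."""


class StatsError(AnalysisError):
    """Statistical routine cannot run (degenerate sample, no predictors)."""
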
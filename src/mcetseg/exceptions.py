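"""Exception hierarchy for mcetseg.

Every failure mode the threshold-search driver needs to distinguish gets its
own class, so callers can skip an infeasible candidate threshold without
masking genuine input errors.
"""


class McetsegError(Exception):
    """Base class for all mcetseg errors."""


class DegenerateImageError(McetsegError):
    """Image is empty, constant, or otherwise unusable for thresholding."""


class EmptyClassError(McetsegError):
    """A candidate threshold leaves one histogram class with no pixels."""


class TrimExceedsClassSizeError(McetsegError):
    """Alpha-trim would remove every pixel of a class (length <= 2*d/2)."""


class UnstableOrderError(McetsegError):
    """Contraharmonic power sums overflowed for an extreme order Q."""


class DegenerateHistogramError(McetsegError):
    """Histogram has fewer than two occupied gray levels."""


class NoFeasibleThresholdError(McetsegError):
    """No candidate threshold is valid under the chosen estimator."""


class UnsupportedEstimatorError(McetsegError):
    """Estimator is recognised (e.g. the lognormal baseline) but not implemented."""


class ZeroDynamicRangeError(McetsegError):
    """Image uniformity is undefined on a constant image (I_max == I_min)."""


class SingleRegionMaskError(McetsegError):
    """Inter-region disparity needs both classes present in the mask."""


class UndefinedMetricError(McetsegError):
    """A supervised metric is undefined (empty prediction or empty truth)."""
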
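"""Minimum cross-entropy threshold selection.

The cross entropy between an image and its two-class segmented version,
with the image-only constant term dropped, leaves the objective

    n(t) = - Σ_{i=1..t} i·h(i)·log μ1(t)  -  Σ_{i=t+1..L} i·h(i)·log μ2(t)

over shifted levels i, where μ1, μ2 are the class means under the chosen
estimator.  The optimal threshold t* is the argmin of n(t) over every
candidate t in [1, L−1] for which both classes are valid.  With the
classical (arithmetic) means this is Li's minimum cross-entropy criterion;
substituting a robust mean estimator changes only μ1, μ2.

Conventions fixed here: natural logarithm; the full candidate range is
swept and infeasible t are skipped (not penalised); ties in n(t) break to
the smallest t.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimatorSpec, estimate_means
from .exceptions import (
    DegenerateHistogramError,
    EmptyClassError,
    NoFeasibleThresholdError,
    TrimExceedsClassSizeError,
    UnstableOrderError,
    UnsupportedEstimatorError,
)
from .histogram import Histogram, apply_threshold, compute_histogram


@dataclass(frozen=True)
class ThresholdResult:
    """Optimal threshold with diagnostics.

    ``objective[t-1]`` holds n(t) for shifted candidate t (NaN where the
    candidate was infeasible under the estimator); ``valid_range`` lists the
    candidates actually evaluated.
    """

    t_raw: int
    t_shifted: int
    mu1: float
    mu2: float
    objective: np.ndarray
    valid_range: np.ndarray
    spec: EstimatorSpec
    warnings: tuple = ()

    def to_dict(self) -> dict:
        return {
            "t_raw": self.t_raw,
            "t_shifted": self.t_shifted,
            "mu1": self.mu1,
            "mu2": self.mu2,
            "spec": str(self.spec),
            "warnings": list(self.warnings),
            "valid_range": self.valid_range.tolist(),
            "objective": [
                None if math.isnan(v) else v for v in self.objective.tolist()
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def mcet_objective(histogram: Histogram, t: int, mu1: float, mu2: float) -> float:
    """Evaluate n(t) for given class means (natural log, shifted levels)."""
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("class means must be positive")
    t = int(t)
    if not 1 <= t <= histogram.L - 1:
        raise ValueError(f"threshold {t} outside [1, {histogram.L - 1}]")
    moments = histogram.levels * histogram.counts
    m1 = float(moments[:t].sum())
    m2 = float(moments[t:].sum())
    return -(m1 * math.log(mu1) + m2 * math.log(mu2))


_SKIPPABLE = (EmptyClassError, TrimExceedsClassSizeError, UnstableOrderError)


def find_threshold(histogram: Histogram, spec: EstimatorSpec) -> ThresholdResult:
    """Exhaustively minimise n(t) over all feasible candidate thresholds.

    Candidates where the estimator fails (empty class, trim larger than the
    class, unstable contraharmonic order) are skipped.  Ties break to the
    smallest t.

    Raises
    ------
    DegenerateHistogramError
        Fewer than two occupied gray levels.
    NoFeasibleThresholdError
        No candidate t is valid under ``spec``.
    UnsupportedEstimatorError
        ``spec`` names a recognised but unimplemented estimator.
    """
    if not spec.supported:
        raise UnsupportedEstimatorError(
            f"estimator {spec.method!r} is not implemented"
        )
    if histogram.n_occupied < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than 2 occupied levels"
        )
    L = histogram.L
    moment_cum = np.cumsum(histogram.levels * histogram.counts).astype(np.float64)
    moment_total = moment_cum[-1]

    objective = np.full(L - 1, np.nan)
    valid_ts = []
    best_t = None
    best_val = math.inf
    best_means = (math.nan, math.nan)
    previous = None  # (mu1, mu2, value) or "skip", reused across empty levels
    for t in range(1, L):
        # Raising t across an unoccupied level leaves both classes
        # unchanged, so n(t) is mathematically constant there; reusing the
        # previous evaluation keeps such stretches exactly flat (ties then
        # break to the smallest t, as documented).
        if t > 1 and histogram.counts[t - 1] == 0 and previous is not None:
            if previous == "skip":
                continue
            mu1, mu2, value = previous
            objective[t - 1] = value
            valid_ts.append(t)
            continue
        try:
            mu1, mu2 = estimate_means(histogram, t, spec)
        except _SKIPPABLE:
            previous = "skip"
            continue
        m1 = moment_cum[t - 1]
        m2 = moment_total - m1
        value = -(m1 * math.log(mu1) + m2 * math.log(mu2))
        previous = (mu1, mu2, value)
        objective[t - 1] = value
        valid_ts.append(t)
        if value < best_val:
            best_val = value
            best_t = t
            best_means = (mu1, mu2)
    if best_t is None:
        raise NoFeasibleThresholdError(
            f"no feasible threshold under spec {spec}"
        )
    warnings = ()
    if best_means[0] >= best_means[1]:
        warnings = (
            f"mu1 >= mu2 at the optimum (mu1={best_means[0]:.4f}, "
            f"mu2={best_means[1]:.4f}); contraharmonic means are not clamped "
            "to their class interval",
        )
    return ThresholdResult(
        t_raw=best_t - 1,
        t_shifted=best_t,
        mu1=best_means[0],
        mu2=best_means[1],
        objective=objective,
        valid_range=np.asarray(valid_ts, dtype=np.int64),
        spec=spec,
        warnings=warnings,
    )


def segment(image, spec: EstimatorSpec) -> tuple[np.ndarray, ThresholdResult]:
    """Histogram → optimal threshold → binary mask, with diagnostics."""
    histogram = compute_histogram(image)
    result = find_threshold(histogram, spec)
    mask = apply_threshold(image, result.t_raw)
    return mask, result
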
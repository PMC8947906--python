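"""Class-mean estimators on histogram mode vectors.

The classical (Gaussian) minimum cross-entropy threshold uses the arithmetic
mean of each histogram class.  Impulse noise (salt at the top of the range,
pepper at the bottom), local outliers and partial-volume "grayness" pixels
all bias that mean; the estimators here are the standard robust mean filters
of image restoration, applied not to spatial windows but to the sorted
multiset of a histogram class:

* ``classical``       — arithmetic mean, Σx / n
* ``alpha_trim``      — arithmetic mean after dropping the d/2 lowest and
                        d/2 highest pixels (robust to mixed impulse+Gaussian)
* ``harmonic``        — n / Σ(1/x); suppresses salt (high) outliers
* ``contraharmonic``  — Σx^(Q+1) / Σx^Q; Q>0 suppresses pepper, Q<0 salt;
                        Q=0 is the arithmetic mean, Q=−1 the harmonic mean
* ``geometric``       — (Πx)^(1/n), computed as exp(mean log x)

The ``lognormal`` method name is accepted in configuration (it appears in the
standard comparison grid) but is a cited baseline, not implemented here.

All values are shifted levels ``>= 1``, so the logs, reciprocals and powers
are well defined.  Public per-mode functions take a mode vector (per-pixel
multiset); :func:`estimate_means` evaluates the same estimator on both
classes directly from histogram counts, which is exact for integer levels
and avoids materialising the multisets inside the threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import (
    EmptyClassError,
    TrimExceedsClassSizeError,
    UnstableOrderError,
    UnsupportedEstimatorError,
)
from .histogram import Histogram

METHODS = ("classical", "alpha_trim", "harmonic", "contraharmonic", "geometric")
#: Recognised in configuration grids but not implementable here.
UNSUPPORTED_METHODS = ("lognormal",)

# Largest exponent magnitude for which 256**(|Q|+1) stays far from float64
# overflow; beyond it the power sums move to the log domain.
_DIRECT_POWER_LIMIT = 120.0


@dataclass(frozen=True)
class EstimatorSpec:
    """Which mean filter to use and its parameter.

    ``half_trim`` (the d/2 of the alpha-trimmed filter) is an absolute pixel
    count, present iff ``method == "alpha_trim"``; ``order`` (Q) is present
    iff ``method == "contraharmonic"``.
    """

    method: str
    half_trim: int | None = None
    order: float | None = None

    def __post_init__(self):
        if self.method not in METHODS + UNSUPPORTED_METHODS:
            raise ValueError(f"unknown estimator method {self.method!r}")
        if self.method == "alpha_trim":
            if self.half_trim is None:
                raise ValueError("alpha_trim requires half_trim (d/2)")
            if isinstance(self.half_trim, bool) or not float(
                self.half_trim
            ).is_integer():
                raise ValueError("half_trim must be an integer pixel count")
            if self.half_trim < 0:
                raise ValueError("half_trim must be >= 0")
            object.__setattr__(self, "half_trim", int(self.half_trim))
        elif self.half_trim is not None:
            raise ValueError(f"half_trim is not a parameter of {self.method}")
        if self.method == "contraharmonic":
            if self.order is None:
                raise ValueError("contraharmonic requires an order Q")
            order = float(self.order)
            if not np.isfinite(order):
                raise ValueError("order Q must be finite")
            object.__setattr__(self, "order", order)
        elif self.order is not None:
            raise ValueError(f"order is not a parameter of {self.method}")

    @property
    def supported(self) -> bool:
        return self.method in METHODS

    @property
    def param(self) -> float | None:
        """The single numeric parameter, if any (d/2 or Q)."""
        if self.method == "alpha_trim":
            return self.half_trim
        if self.method == "contraharmonic":
            return self.order
        return None

    def __str__(self) -> str:
        if self.param is None:
            return self.method
        return f"{self.method}:{self.param:g}"

    @classmethod
    def parse(cls, text: str) -> "EstimatorSpec":
        """Parse ``"<method>[:<param>]"``, e.g. ``"alpha_trim:50"``,
        ``"contraharmonic:-0.5"``, ``"classical"``."""
        method, _, param = text.strip().partition(":")
        method = method.strip()
        if not param:
            return cls(method=method)
        if method == "alpha_trim":
            value = float(param)
            if not value.is_integer():
                raise ValueError(f"half_trim must be an integer, got {param!r}")
            return cls(method=method, half_trim=int(value))
        if method == "contraharmonic":
            return cls(method=method, order=float(param))
        raise ValueError(f"{method!r} takes no parameter (got {param!r})")


# ---------------------------------------------------------------------------
# Per-mode (multiset) estimators — the public reference forms.


def _validated(mode) -> np.ndarray:
    values = np.asarray(mode, dtype=np.float64).ravel()
    if values.size == 0:
        raise EmptyClassError("empty class")
    if (values < 1).any():
        raise ValueError("mode values must be shifted levels >= 1")
    return values


def classical_mean(mode) -> float:
    """Arithmetic mean of the mode; equals the count-weighted histogram mean."""
    values = _validated(mode)
    return float(values.sum() / values.size)


def alpha_trimmed_mean(mode, half_trim: int) -> float:
    """Mean after removing the ``half_trim`` lowest and highest pixels.

    Trimming is positional on the sorted multiset — exactly d/2 entries are
    removed from each end regardless of duplicated values.
    """
    values = np.sort(_validated(mode))
    if isinstance(half_trim, bool) or int(half_trim) != half_trim or half_trim < 0:
        raise ValueError("half_trim must be a non-negative integer")
    half_trim = int(half_trim)
    remaining = values.size - 2 * half_trim
    if remaining < 1:
        raise TrimExceedsClassSizeError(
            f"trim {half_trim} exceeds class size {values.size}"
        )
    kept = values[half_trim : values.size - half_trim]
    return float(kept.sum() / remaining)


def harmonic_mean(mode) -> float:
    """n / Σ(1/x): pulled toward the low end, hence insensitive to salt."""
    values = _validated(mode)
    return float(values.size / (1.0 / values).sum())


def contraharmonic_mean(mode, order: float) -> float:
    """Σx^(Q+1) / Σx^Q for order Q; may leave [min, max] for extreme Q."""
    values = _validated(mode)
    order = float(order)
    if not np.isfinite(order):
        raise ValueError("order Q must be finite")
    if abs(order) + 1 <= _DIRECT_POWER_LIMIT:
        num = (values ** (order + 1)).sum()
        den = (values ** order).sum()
        if np.isfinite(num) and np.isfinite(den) and den > 0:
            return float(num / den)
    logv = np.log(values)
    result = float(np.exp(logsumexp((order + 1) * logv) - logsumexp(order * logv)))
    if not np.isfinite(result):
        raise UnstableOrderError(f"unstable order Q={order}")
    return result


def geometric_mean(mode) -> float:
    """(Πx)^(1/n), via exp(mean log x) to avoid overflow."""
    values = _validated(mode)
    return float(np.exp(np.log(values).mean()))


def mode_mean(mode, spec: EstimatorSpec) -> float:
    """Apply the estimator described by ``spec`` to one mode vector."""
    if spec.method == "classical":
        return classical_mean(mode)
    if spec.method == "alpha_trim":
        return alpha_trimmed_mean(mode, spec.half_trim)
    if spec.method == "harmonic":
        return harmonic_mean(mode)
    if spec.method == "contraharmonic":
        return contraharmonic_mean(mode, spec.order)
    if spec.method == "geometric":
        return geometric_mean(mode)
    raise UnsupportedEstimatorError(f"estimator {spec.method!r} is not implemented")


# ---------------------------------------------------------------------------
# Count-weighted forms used inside the threshold sweep.  For integer counts
# and levels these agree exactly with the multiset forms above (the power
# sums are sums of identical float terms).


def _power_sum(levels: np.ndarray, counts: np.ndarray, q: float) -> float:
    if abs(q) <= _DIRECT_POWER_LIMIT:
        s = float(np.dot(counts, levels ** q))
        if np.isfinite(s):
            return s
    m = counts > 0
    return float(
        np.exp(logsumexp(q * np.log(levels[m]), b=counts[m].astype(np.float64)))
    )


def _trimmed_weighted_mean(
    levels: np.ndarray, counts: np.ndarray, half_trim: int
) -> float:
    n = int(counts.sum())
    remaining = n - 2 * half_trim
    if remaining < 1:
        raise TrimExceedsClassSizeError(f"trim {half_trim} exceeds class size {n}")
    cum = np.cumsum(counts)
    value_cum = np.cumsum(counts * levels)

    def sum_of_smallest(k: int) -> float:
        # Sum of the k smallest pixels of the class; exact for integers.
        if k == 0:
            return 0.0
        j = int(np.searchsorted(cum, k))
        below = cum[j - 1] if j > 0 else 0
        value_below = value_cum[j - 1] if j > 0 else 0
        return float(value_below + (k - below) * levels[j])

    return (sum_of_smallest(n - half_trim) - sum_of_smallest(half_trim)) / remaining


def _weighted_mean(levels: np.ndarray, counts: np.ndarray, spec: EstimatorSpec) -> float:
    n = float(counts.sum())
    flevels = levels.astype(np.float64)
    if spec.method == "classical":
        return float(np.dot(counts, flevels) / n)
    if spec.method == "alpha_trim":
        return _trimmed_weighted_mean(levels, counts, spec.half_trim)
    if spec.method == "harmonic":
        return n / _power_sum(flevels, counts, -1.0)
    if spec.method == "contraharmonic":
        num = _power_sum(flevels, counts, spec.order + 1.0)
        den = _power_sum(flevels, counts, spec.order)
        if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
            raise UnstableOrderError(f"unstable order Q={spec.order}")
        result = num / den
        if not np.isfinite(result):
            raise UnstableOrderError(f"unstable order Q={spec.order}")
        return float(result)
    if spec.method == "geometric":
        return float(np.exp(np.dot(counts, np.log(flevels)) / n))
    raise UnsupportedEstimatorError(f"estimator {spec.method!r} is not implemented")


def estimate_means(
    histogram: Histogram, t: int, spec: EstimatorSpec
) -> tuple[float, float]:
    """Estimate (μ1, μ2) at shifted threshold ``t``.

    The same filter with the same parameter is applied to both classes.
    Raises :class:`EmptyClassError` if either class is empty, and propagates
    estimator-specific errors (trim too large, unstable order); the search
    driver treats any of these as "candidate t invalid".
    """
    t = int(t)
    if not 1 <= t <= histogram.L - 1:
        raise ValueError(f"threshold {t} outside [1, {histogram.L - 1}]")
    counts = histogram.counts
    levels = histogram.levels
    if counts[:t].sum() == 0 or counts[t:].sum() == 0:
        raise EmptyClassError(f"empty class at t={t}")
    mu1 = _weighted_mean(levels[:t], counts[:t], spec)
    mu2 = _weighted_mean(levels[t:], counts[t:], spec)
    return mu1, mu2
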
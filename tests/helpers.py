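"""Independent reference implementations and random input builders.

The oracle works on the expanded per-pixel multiset of the histogram and
evaluates the objective by plain sums over mode values, deliberately
avoiding the package's count-weighted prefix-sum route.
"""

from __future__ import annotations

import math

import numpy as np

from mcetseg.estimators import EstimatorSpec
from mcetseg.histogram import Histogram, L_LEVELS


# ---------------------------------------------------------------------------
# Oracle: exhaustive minimum cross-entropy threshold on the pixel multiset.


def oracle_mode_mean(values: np.ndarray, spec: EstimatorSpec) -> float:
    """Mean of a sorted pixel-value vector, straight from the definitions."""
    v = values.astype(np.float64)
    n = v.size
    if spec.method == "classical":
        return v.sum() / n
    if spec.method == "alpha_trim":
        d2 = spec.half_trim
        if n - 2 * d2 < 1:
            raise ValueError("trim too large")
        kept = np.sort(v)[d2 : n - d2]
        return kept.sum() / kept.size
    if spec.method == "harmonic":
        return n / (1.0 / v).sum()
    if spec.method == "contraharmonic":
        q = spec.order
        return (v ** (q + 1)).sum() / (v ** q).sum()
    if spec.method == "geometric":
        return math.exp(np.log(v).sum() / n)
    raise ValueError(spec.method)


def oracle_find_threshold(hist: Histogram, spec: EstimatorSpec):
    """Exhaustive argmin of n(t); returns (t_shifted, mu1, mu2) or None.

    n(t) = -Σ_{i<=t} i·h(i)·log μ1 - Σ_{i>t} i·h(i)·log μ2, and on the
    per-pixel multiset Σ i·h(i) over a class is simply the sum of the
    class's pixel values.
    """
    pixels = np.repeat(hist.levels, hist.counts)
    best = None
    for t in range(1, hist.L):
        k = int(np.searchsorted(pixels, t, side="right"))
        mode1, mode2 = pixels[:k], pixels[k:]
        if mode1.size == 0 or mode2.size == 0:
            continue
        try:
            mu1 = oracle_mode_mean(mode1, spec)
            mu2 = oracle_mode_mean(mode2, spec)
        except ValueError:
            continue
        value = -(
            float(mode1.sum()) * math.log(mu1)
            + float(mode2.sum()) * math.log(mu2)
        )
        if best is None or value < best[0]:
            best = (value, t, mu1, mu2)
    if best is None:
        return None
    return best[1], best[2], best[3]


def oracle_inter_region_disparity(image: np.ndarray, mask: np.ndarray) -> float:
    """Per-pixel double-loop evaluation of the disparity score (3x3 window)."""
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    h, w = img.shape
    score = 0.0
    for region_value in (False, True):
        region_pixels = []
        border_pixels = []
        for y in range(h):
            for x in range(w):
                if mask[y, x] != region_value:
                    continue
                in_contrasts, out_contrasts = [], []
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == 0 and dx == 0:
                            continue
                        ny, nx = y + dy, x + dx
                        if not (0 <= ny < h and 0 <= nx < w):
                            continue
                        c = abs(img[y, x] - img[ny, nx]) / (L_LEVELS - 1)
                        if mask[ny, nx] == region_value:
                            in_contrasts.append(c)
                        else:
                            out_contrasts.append(c)
                region_pixels.append(max(in_contrasts, default=0.0))
                if out_contrasts:
                    border_pixels.append(max(out_contrasts))
        area = len(region_pixels)
        ci = sum(region_pixels) / area
        ce = sum(border_pixels) / len(border_pixels)
        if ci == 0.0:
            cr = ce
        elif ci < ce:
            cr = 1.0 - ci / ce
        else:
            cr = 0.0
        score += (area / (h * w)) * cr
    return score


# ---------------------------------------------------------------------------
# Random input builders


def random_histogram(rng: np.random.Generator, kind: str | None = None,
                     total: int = 2000) -> Histogram:
    """Seeded random histogram of a given shape family."""
    if kind is None:
        kind = rng.choice(["spikes", "uniform", "bimodal", "noisy_bimodal"])
    counts = np.zeros(L_LEVELS, dtype=np.int64)
    if kind == "spikes":
        n_spikes = int(rng.integers(2, 6))
        levels = rng.choice(L_LEVELS, size=n_spikes, replace=False)
        weights = rng.dirichlet(np.ones(n_spikes))
        for lev, wgt in zip(levels, weights):
            counts[lev] += max(1, int(round(wgt * total)))
    elif kind == "uniform":
        lo, hi = sorted(rng.choice(L_LEVELS, size=2, replace=False))
        hi = max(hi, lo + 1)
        samples = rng.integers(lo, hi + 1, size=total)
        counts += np.bincount(samples, minlength=L_LEVELS)
    else:
        mu1 = rng.uniform(30, 100)
        mu2 = rng.uniform(mu1 + 40, 230)
        sigma = rng.uniform(5, 25)
        n1 = int(total * rng.uniform(0.3, 0.7))
        samples = np.concatenate([
            rng.normal(mu1, sigma, n1),
            rng.normal(mu2, sigma, total - n1),
        ])
        samples = np.clip(np.rint(samples), 0, 255).astype(np.int64)
        counts += np.bincount(samples, minlength=L_LEVELS)
        if kind == "noisy_bimodal":
            counts[0] += int(total * 0.03)
            counts[L_LEVELS - 1] += int(total * 0.03)
    return Histogram(counts=counts)


def random_bimodal_image(rng: np.random.Generator, side: int = 32) -> np.ndarray:
    """Small random two-class image with Gaussian class noise."""
    truth = rng.random((side, side)) < 0.4
    image = np.where(truth, rng.normal(180, 15, truth.shape),
                     rng.normal(60, 15, truth.shape))
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def random_mode(rng: np.random.Generator, max_len: int = 200) -> np.ndarray:
    """Random sorted mode vector of shifted levels in [1, 256]."""
    n = int(rng.integers(1, max_len + 1))
    return np.sort(rng.integers(1, L_LEVELS + 1, size=n))
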
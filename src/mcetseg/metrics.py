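"""Segmentation quality metrics.

Unsupervised (no reference needed):

* image uniformity (IU): 1 minus the summed within-region intensity
  variances normalised by half the squared dynamic range (Levine–Nazif);
* region contrast (RC): |μ1 − μ2| / (μ1 + μ2);
* inter-region disparity (IRD): compares each region's interior pixel
  contrast with its contrast across the region border.

Supervised (against a ground-truth mask): Jaccard index, F-score and pixel
accuracy from the TP/FP/FN/TN confusion counts.  All six scores lie in
[0, 1], 1 meaning a good segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    EmptyClassError,
    SingleRegionMaskError,
    UndefinedMetricError,
    ZeroDynamicRangeError,
)
from .histogram import L_LEVELS, as_gray_image


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """All six scores; supervised entries are None without ground truth."""

    iu: float
    rc: float
    ird: float
    jaccard: float | None = None
    f_score: float | None = None
    accuracy: float | None = None

    def as_dict(self) -> dict:
        return {
            "IU": self.iu,
            "RC": self.rc,
            "IRD": self.ird,
            "JI": self.jaccard,
            "F": self.f_score,
            "ACC": self.accuracy,
        }


# ---------------------------------------------------------------------------
# Unsupervised metrics


def _region_split(image: np.ndarray, mask: np.ndarray):
    r1 = image[mask == 0]
    r2 = image[mask == 1]
    if r1.size == 0 or r2.size == 0:
        raise EmptyClassError("a region is empty")
    return r1, r2


def image_uniformity(image, t_raw: int) -> float:
    """Levine–Nazif uniformity of the two threshold-induced regions.

    ``IU = 1 − (σ1² + σ2²)/Z`` with population variances and normaliser
    ``Z = (I_max − I_min)² / 2`` over the whole image; clipped to [0, 1].
    """
    arr = as_gray_image(image)
    i_min, i_max = int(arr.min()), int(arr.max())
    if i_max == i_min:
        raise ZeroDynamicRangeError("constant image: uniformity undefined")
    mask = (arr > int(t_raw)).astype(np.uint8)
    r1, r2 = _region_split(arr, mask)
    z = (i_max - i_min) ** 2 / 2.0
    value = 1.0 - (float(np.var(r1)) + float(np.var(r2))) / z
    return float(np.clip(value, 0.0, 1.0))


def region_contrast(mu1: float, mu2: float) -> float:
    """Normalised separation of the two class means: |μ1 − μ2|/(μ1 + μ2)."""
    if mu1 + mu2 <= 0:
        raise ValueError("mean sum must be positive")
    return float(abs(mu1 - mu2) / (mu1 + mu2))


_OFFSETS_8 = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]
_OFFSETS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def inter_region_disparity(image, mask, connectivity: int = 8) -> float:
    """Interior-vs-exterior contrast score of a two-region segmentation.

    Pixel contrast is ``c(s, u) = |I(s) − I(u)| / (L − 1)``.  For region Ri,
    the interior contrast CI(i) averages, over all region pixels, the
    maximum contrast to a same-region neighbour; the exterior contrast CE(i)
    averages, over the border pixels Fi (region pixels with a neighbour
    outside Ri), the maximum contrast to an out-of-region neighbour.  The
    region score is ``1 − CI/CE`` if 0 < CI < CE, ``CE`` if CI = 0, else 0;
    the reported scalar is the region-size-weighted average of the two.

    The neighbourhood W(s) is the 3×3 (8-connected) window by default;
    ``connectivity=4`` selects the cross-shaped window.
    """
    arr = as_gray_image(image).astype(np.float64)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape must match image shape")
    if mask.all() or (~mask).all():
        raise SingleRegionMaskError("mask holds a single region")
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4

    h, w = arr.shape
    max_in = np.zeros((h, w))
    max_out = np.zeros((h, w))
    has_out = np.zeros((h, w), dtype=bool)
    for dy, dx in offsets:
        src = (slice(max(-dy, 0), h - max(dy, 0)), slice(max(-dx, 0), w - max(dx, 0)))
        dst = (slice(max(dy, 0), h - max(-dy, 0)), slice(max(dx, 0), w - max(-dx, 0)))
        contrast = np.abs(arr[src] - arr[dst]) / (L_LEVELS - 1)
        same = mask[src] == mask[dst]
        np.maximum(max_in[src], np.where(same, contrast, 0.0), out=max_in[src])
        np.maximum(max_out[src], np.where(same, 0.0, contrast), out=max_out[src])
        has_out[src] |= ~same

    total = arr.size
    score = 0.0
    for region_value in (False, True):
        region = mask == region_value
        area = int(region.sum())
        ci = float(max_in[region].sum()) / area
        border = region & has_out
        ce = float(max_out[border].sum()) / int(border.sum())
        if ci == 0.0:
            cr = ce
        elif ci < ce:
            cr = 1.0 - ci / ce
        else:
            cr = 0.0
        score += (area / total) * cr
    return float(score)


# ---------------------------------------------------------------------------
# Supervised metrics


def confusion(mask, truth) -> ConfusionCounts:
    """TP/FP/FN/TN between a predicted mask and a ground-truth mask."""
    mask = np.asarray(mask).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if mask.shape != truth.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(mask & truth))
    fp = int(np.count_nonzero(mask & ~truth))
    fn = int(np.count_nonzero(~mask & truth))
    tn = mask.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def supervised_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(Jaccard, F-score, accuracy) from confusion counts.

    Jaccard = TP/(TP+FP+FN); F = 2PR/(P+R) with precision P = TP/(TP+FP)
    and recall R = TP/(TP+FN); accuracy = (TP+TN)/total.  An empty
    prediction (TP+FP = 0) or empty truth (TP+FN = 0) leaves precision or
    recall undefined and raises :class:`UndefinedMetricError` rather than
    silently scoring 0.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tp + fp == 0:
        raise UndefinedMetricError("empty prediction: precision undefined")
    if tp + fn == 0:
        raise UndefinedMetricError("empty truth: recall undefined")
    jaccard = tp / (tp + fp + fn)
    if tp == 0:
        f_score = 0.0  # limit of 2PR/(P+R) as both P and R vanish
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f_score = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / counts.total
    return float(jaccard), float(f_score), float(accuracy)


def evaluate_segmentation(
    image, mask, mu1: float, mu2: float, t_raw: int, truth=None
) -> MetricsReport:
    """Bundle the unsupervised (and, given truth, supervised) scores."""
    iu = image_uniformity(image, t_raw)
    rc = region_contrast(mu1, mu2)
    ird = inter_region_disparity(image, mask)
    if truth is None:
        return MetricsReport(iu=iu, rc=rc, ird=ird)
    jaccard, f_score, accuracy = supervised_metrics(confusion(mask, truth))
    return MetricsReport(
        iu=iu, rc=rc, ird=ird, jaccard=jaccard, f_score=f_score, accuracy=accuracy
    )
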
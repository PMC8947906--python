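"""Gray-level histograms, mode vectors and binary masks.

All estimator and objective computations work on *shifted* gray levels
``i = raw + 1`` in ``[1, L]`` (``L = 256`` for 8-bit images).  The shift keeps
``log(i)``, ``1/i`` and ``i**Q`` well defined at raw intensity 0; thresholds
are converted back to the raw scale (``t_raw = t_shifted - 1``) on output.

A *mode vector* is the sorted multiset of shifted intensities of one
histogram class at a candidate threshold: level ``i`` appears ``counts[i]``
times, i.e. once per pixel.  This per-pixel convention is what makes the
zero-trim and zero-order estimators reduce exactly to the classical
count-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateImageError, EmptyClassError

L_LEVELS = 256


def as_gray_image(image) -> np.ndarray:
    """Validate and return an 8-bit single-channel image as a 2-D int array.

    Raises
    ------
    DegenerateImageError
        If the array is empty.
    ValueError
        If the array is not 2-D or holds values outside [0, 255].
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise DegenerateImageError("empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError("image must hold integer intensities")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr.astype(np.int64, copy=False)


@dataclass(frozen=True)
class Histogram:
    """Per-gray-level pixel counts over shifted levels ``[1, L]``.

    ``counts[k]`` is the number of pixels at shifted level ``k + 1``
    (raw intensity ``k``).
    """

    counts: np.ndarray
    L: int = L_LEVELS

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.L,):
            raise ValueError(f"counts must have shape ({self.L},)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def levels(self) -> np.ndarray:
        """Shifted gray levels ``1..L`` aligned with ``counts``."""
        return np.arange(1, self.L + 1, dtype=np.int64)

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


def compute_histogram(image) -> Histogram:
    """Count pixels per gray level; shifted level ``i`` holds raw intensity ``i-1``."""
    arr = as_gray_image(image)
    counts = np.bincount(arr.ravel(), minlength=L_LEVELS)
    return Histogram(counts=counts)


def split_modes(histogram: Histogram, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a histogram at shifted threshold ``t`` into two mode vectors.

    Mode 1 holds every pixel with level ``<= t``, mode 2 every pixel with
    level ``> t``; each is a sorted per-pixel multiset of shifted levels.

    Raises
    ------
    ValueError
        If ``t`` is outside ``[1, L-1]``.
    EmptyClassError
        If either mode holds no pixels (the search driver skips such ``t``).
    """
    t = int(t)
    if not 1 <= t <= histogram.L - 1:
        raise ValueError(f"threshold {t} outside [1, {histogram.L - 1}]")
    levels = histogram.levels
    counts = histogram.counts
    mode1 = np.repeat(levels[:t], counts[:t])
    mode2 = np.repeat(levels[t:], counts[t:])
    if mode1.size == 0 or mode2.size == 0:
        raise EmptyClassError(f"empty class at t={t}")
    return mode1, mode2


def apply_threshold(image, t_raw: int) -> np.ndarray:
    """Binarise: 1 where raw intensity is strictly above ``t_raw``, else 0.

    Ties at the threshold go to background (strict ``>``).
    """
    arr = as_gray_image(image)
    t_raw = int(t_raw)
    if not 0 <= t_raw <= 255:
        raise ValueError(f"raw threshold {t_raw} outside [0, 255]")
    return (arr > t_raw).astype(np.uint8)
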
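"""Image readers and mask writers (8-bit grayscale PNG / TIFF / PGM).

Multi-channel inputs are rejected outright: a silent RGB-to-gray conversion
would change the histogram the whole method runs on.  Masks are written as
8-bit PNG with values {0, 255}, object pixels at 255.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .histogram import as_gray_image

READABLE_SUFFIXES = (".png", ".tif", ".tiff", ".pgm")


def read_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit grayscale image; reject colour/alpha channels."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: multi-channel image ({arr.shape[-1]} channels); "
            "convert to single-channel grayscale explicitly before use"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return as_gray_image(arr)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask stored as {0, 255} (or {0, 1}) grayscale."""
    arr = read_gray_image(path)
    values = np.unique(arr)
    if not np.isin(values, (0, 1, 255)).all():
        raise ValueError(f"{path}: not a binary mask (values {values[:10]})")
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a {0,1} mask as 8-bit PNG with object pixels at 255."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must contain only 0 and 1")
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def write_gray_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write an 8-bit grayscale image."""
    iio.imwrite(path, as_gray_image(image).astype(np.uint8))
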
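"""Seeded synthetic bimodal images with known ground truth.

The generator emulates the nuisance structure that robust mean estimation
targets in a bimodal grayscale image: Gaussian within-class noise, impulse
(salt-and-pepper) corruption that piles up at the two ends of the
histogram, and an optional "grayness" band of intermediate intensities at
the object boundary (the partial-volume pixels that bias a classical class
mean).  Foreground is brighter than background by convention (above-
threshold pixels map to the object); an ``invert`` flag accommodates
dark-lesion imagery.

Defaults describe the reference study condition used throughout the test
suite: a 128×128 image, class means 60/180, σ = 15 in both classes, disk
foreground, no impulses.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from .estimators import EstimatorSpec


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image + ground-truth pair."""

    height: int = 128
    width: int = 128
    bg_mean: float = 60.0
    fg_mean: float = 180.0
    bg_sigma: float = 15.0
    fg_sigma: float = 15.0
    salt_density: float = 0.0
    pepper_density: float = 0.0
    grayzone_width: int = 0
    shape: str = "disk"
    seed: int = 0
    invert: bool = False

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be >= 1")
        if not 0 <= self.bg_mean < self.fg_mean <= 255:
            raise ValueError("need 0 <= bg_mean < fg_mean <= 255")
        if self.bg_sigma < 0 or self.fg_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        for d in (self.salt_density, self.pepper_density):
            if not 0 <= d <= 0.5:
                raise ValueError("impulse densities must lie in [0, 0.5]")
        if self.salt_density + self.pepper_density >= 1:
            raise ValueError("salt + pepper density must be < 1")
        if self.grayzone_width < 0:
            raise ValueError("grayzone_width must be >= 0")
        if self.shape not in ("disk", "rectangle", "blob"):
            raise ValueError(f"unknown shape {self.shape!r}")


def _object_support(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.shape == "disk":
        radius = 0.3 * min(h, w)
        return ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2) <= radius**2
    if spec.shape == "rectangle":
        return (
            (yy >= h // 4) & (yy < h - h // 4) & (xx >= w // 4) & (xx < w - w // 4)
        )
    # blob: threshold a smoothed random field at its 70th percentile,
    # giving an irregular connected-ish foreground of ~30% area
    field = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=max(min(h, w) / 8.0, 1.0)
    )
    return field >= np.quantile(field, 0.7)


def generate(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the image and its noiseless ground-truth mask.

    Deterministic for a fixed seed: one seed sequence drives three
    independent child streams (shape, Gaussian noise, impulses), so e.g.
    changing the impulse densities does not reshuffle the class noise.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    shape_rng, noise_rng, impulse_rng = (np.random.default_rng(s) for s in seeds)

    truth = _object_support(spec, shape_rng)
    base = np.where(truth, float(spec.fg_mean), float(spec.bg_mean))

    if spec.grayzone_width > 0 and truth.any() and (~truth).any():
        # signed distance to the object boundary, positive inside
        dist = ndimage.distance_transform_edt(truth) - ndimage.distance_transform_edt(
            ~truth
        )
        frac = np.clip(dist / spec.grayzone_width + 0.5, 0.0, 1.0)
        base = spec.bg_mean + (spec.fg_mean - spec.bg_mean) * frac

    sigma = np.where(truth, spec.fg_sigma, spec.bg_sigma)
    image = base + noise_rng.standard_normal(base.shape) * sigma
    image = np.rint(np.clip(image, 0, 255))

    u = impulse_rng.random(image.shape)
    image[u < spec.pepper_density] = 0
    image[u >= 1.0 - spec.salt_density] = 255

    image = image.astype(np.uint8)
    if spec.invert:
        image = (255 - image.astype(np.int64)).astype(np.uint8)
    return image, truth.astype(np.uint8)


#: Grid parameters of the standard 22-configuration estimator sweep.
CONTRAHARMONIC_ORDERS = (-3.0, -1.0, -0.5, 0.0, 0.1)
ALPHA_TRIM_HALVES = (10, 20, 30, 40, 50, 55, 60, 65, 70, 80, 90, 100, 110)


def sweep_grid() -> list[EstimatorSpec]:
    """The standard 22-configuration estimator grid.

    Classical mean, the lognormal-distribution baseline (present in the
    grid for completeness but flagged unsupported), harmonic, geometric,
    five contraharmonic orders and thirteen alpha-trim values.
    """
    grid = [
        EstimatorSpec("classical"),
        EstimatorSpec("lognormal"),
        EstimatorSpec("harmonic"),
        EstimatorSpec("geometric"),
    ]
    grid += [EstimatorSpec("contraharmonic", order=q) for q in CONTRAHARMONIC_ORDERS]
    grid += [EstimatorSpec("alpha_trim", half_trim=d) for d in ALPHA_TRIM_HALVES]
    return grid


def materialize(
    specs: list[FixtureSpec], outdir: str | os.PathLike
) -> list[dict]:
    """Write PNG pairs (``img_NNN.png`` + ``img_NNN_gt.png``) and a JSON
    manifest of the specs; returns the manifest entries."""
    from .io import write_gray_image, write_mask

    os.makedirs(outdir, exist_ok=True)
    manifest = []
    for k, spec in enumerate(specs):
        image, truth = generate(spec)
        stem = f"img_{k:03d}"
        write_gray_image(os.path.join(outdir, f"{stem}.png"), image)
        write_mask(os.path.join(outdir, f"{stem}_gt.png"), truth)
        manifest.append({"image": f"{stem}.png", "truth": f"{stem}_gt.png",
                         **asdict(spec)})
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
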
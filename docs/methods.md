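# Methods

## Model

The package treats a grayscale image as a sample from a two-class intensity
mixture and selects a single global threshold by minimum cross entropy.
All internal computation uses shifted gray levels `i = raw + 1 ∈ [1, 256]`,
so that `log i`, `1/i` and `i^Q` are defined at raw intensity 0; reported
thresholds are converted back (`t_raw = t_shifted − 1`). With histogram
`h(i)`, the minimised objective is

    n(t) = − m₁(t)·log μ₁(t) − m₂(t)·log μ₂(t)

where `m₁(t) = Σ_{i≤t} i·h(i)` and `m₂(t) = Σ_{i>t} i·h(i)` are the class
first moments and `μ₁, μ₂` the class means under the chosen estimator. For
the arithmetic means this is Li's classical cross-entropy criterion; the
contribution implemented here is the substitution of robust mean filters
(alpha-trimmed, harmonic, contraharmonic of order Q, geometric) for the
arithmetic mean, evaluated on the sorted per-pixel multiset of each
histogram class.

The per-pixel (count-weighted) reading of a histogram class is load-bearing:
it is what makes `alpha_trim` with `d/2 = 0` and `contraharmonic` with
`Q = 0` reduce *exactly* to the classical weighted mean, and `Q = −1` to the
harmonic mean. These reductions hold bitwise in the implementation (the
sweep computes both sides from identical floating-point sums) and are
enforced by tests.

## Threshold search

`find_threshold` evaluates `n(t)` for every candidate `t ∈ [1, 255]`.
Candidates where an estimator is undefined — an empty class, a trim `d/2`
that exceeds a class size, an overflowing contraharmonic order — are
skipped, not penalised. Ties break to the smallest `t`.

Two numerical choices matter:

* **Flat stretches are exactly flat.** Raising `t` across an unoccupied
  gray level does not change either class, so `n(t)` is mathematically
  constant there; the sweep reuses the previous evaluation instead of
  recomputing it from differently-sized array slices. Without this, last-bit
  rounding differences (~1e−10 on an objective of magnitude ~1e6) would
  break mathematical ties arbitrarily deep inside the empty valley of a
  well-separated histogram. With it, the argmin is the left edge of the
  best flat stretch, matching an exact-arithmetic tie-break.
* **Contraharmonic power sums** use direct float powers while
  `(|Q|+1)·log 256` is safely below the float64 overflow threshold
  (|Q| ≲ 120) and switch to a log-sum-exp evaluation beyond; a non-finite
  result raises an "unstable order" error. Contraharmonic means are not
  clamped into their class interval; if `μ1 ≥ μ2` at the optimum, a warning
  is attached to the result rather than silently reordering.

The search is O(L²)-ish with tiny constants (a few ms per histogram): each
candidate does O(L) vectorised work on count arrays. The per-pixel mode
vectors are materialised only in the public API (`split_modes`, the
per-mode mean functions) and in the independent test oracle, which sweeps
the expanded pixel multiset directly — keeping the two routes separate is
what makes the oracle equivalence test meaningful.

## Evaluation metrics

Unsupervised: region uniformity `IU = 1 − (σ₁² + σ₂²)/Z` with *population*
variances of the two threshold-induced regions (regions are complete pixel
populations, not samples) and `Z = (I_max − I_min)²/2`, clipped to [0, 1];
region contrast `RC = |μ₁ − μ₂|/(μ₁ + μ₂)`; inter-region disparity compares
each region's mean maximum interior pixel contrast `CI` against its mean
maximum border contrast `CE` (contrast `c(s,u) = |I(s) − I(u)|/255`),
scoring `1 − CI/CE` if `0 < CI < CE`, `CE` if `CI = 0`, else 0, and reports
the region-size-weighted average. The neighbourhood is the 8-connected 3×3
window (4-connected available via an argument); the border of a region is
its pixels with at least one neighbour outside the region. Normalisers are
pixel counts (region area, border length).

Supervised: Jaccard `TP/(TP+FP+FN)`, F-score `2PR/(P+R)`, accuracy
`(TP+TN)/N`. An empty prediction or empty truth leaves precision or recall
undefined and raises a distinct error instead of returning 0, so batch
averages stay honest; the `TP = 0` with both `FP, FN > 0` case returns the
limit value 0. The identity `J = F/(2 − F)` is asserted in tests.

## Synthetic data

`FixtureSpec`/`generate` emulate exactly the nuisance structure the robust
estimators target, and nothing more: a brighter foreground shape (disk,
centered rectangle, or thresholded smoothed-noise blob) on a darker
background, independent Gaussian intensity noise per class, optional
salt (→255) and pepper (→0) impulses placed uniformly at random, and an
optional linear "grayness" ramp between the class means over a band of
given width around the object boundary (ground truth unchanged). Rounding
to 8 bits happens after clipping; impulses are applied last. One integer
seed drives three independent child streams (shape, Gaussian noise,
impulses), so outputs are bit-reproducible and changing one noise knob does
not reshuffle the others.

Defaults — 128×128, class means 60/180, σ = 15 in both classes, disk
foreground (~28% area), no impulses, no grayness — are the reference study
condition used by the test suite and the acceptance script. The impulse
densities used in the robustness experiments (3% salt + 3% pepper) and the
grayness width (4 px) are set per experiment. What the generator does *not*
emulate: MRI bias fields and Rician noise, dermoscopy artifacts (hairs,
rulers), spatially correlated texture, multi-class anatomy. Passing tests
therefore demonstrate correctness of the method on its own model
assumptions (bimodal + impulse/Gaussian nuisance), not clinical
performance.

## Batch layer and grid

`sweep_grid()` returns the standard 22-configuration comparison grid:
classical; the lognormal-distribution baseline (kept in the grid so batch
tables retain their standard shape, but flagged unsupported — it is a cited
comparison method, not part of this package); harmonic; geometric;
contraharmonic `Q ∈ {−3, −1, −0.5, 0, 0.1}`; alpha-trim
`d/2 ∈ {10, 20, 30, 40, 50, 55, 60, 65, 70, 80, 90, 100, 110}`. The trim
values are absolute pixel counts and scale with image area (a 128×128 →
256×256 resize should double them); the library takes absolute counts and
leaves any scaling to the caller. `Q` is accepted as any finite real.

Batch runs are deterministic and order-stable; the optional joblib
parallelism changes only wall-clock time, never values or row order
(asserted byte-for-byte in tests).

## Known limitations and observed behaviour

* Single threshold only; no multilevel extension.
* 8-bit single-channel 2-D images only; colour inputs are rejected rather
  than converted.
* On well-separated bimodal fixtures (means 120 levels apart, σ = 15) the
  histogram valley is nearly empty, and *any* threshold inside it yields
  essentially the same mask. Two consequences, both visible in the
  acceptance report: symmetric salt+pepper noise barely moves the classical
  threshold (the two impulse spikes pull μ₁ and μ₂ in opposite directions),
  and alpha-trimming shifts the argmin a few levels left even on clean
  images (the trim window always removes the boundary-adjacent pixels of
  each mode). So on such fixtures the trimmed estimator does not reduce
  threshold deviation relative to classical, and segmentation accuracy is
  statistically indistinguishable between estimators — the impulse pixels
  themselves, which no global threshold can reclassify, dominate the error.
  The estimators differentiate on histograms whose classes overlap or are
  asymmetrically contaminated.
* The acceptance script's problem sizes (50-replicate recovery and
  robustness runs, 50 histograms × 21 configs against the exhaustive
  reference, 20-image noisy sweep) were chosen to characterise the method's
  behaviour at desk scale with stable statistics.
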
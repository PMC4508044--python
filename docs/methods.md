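# Methods

## Benchmark model

A benchmark image is `X(r, b, n) = f(g_b · (1 − s_b · d(i, j)) · X_r + E_n)`
where `X_r` is the rendered clean scene, the multiplicative factor is the
shading field, `E_n` is iid Gaussian noise and `f` clips to `[0, 255]`.
Operations apply in the order render → shade → add noise → clip → quantize,
i.e. noise is added to the already-shaded image, and arithmetic is
continuous until the final round-half-up to the 8-bit storage grid at file
write.

**Shading.** Real shading comes from moving or dimming light sources; we
simulate it with a planar model: a global gain `g_b` and a linear fall-off
with normalized distance `d(i, j)` from a simulated light anchor (default:
the top-left corner; `d` is normalized by the image diagonal, so `d ∈ [0,
1]`). The default schedules are linear over the 13 grades: `g_b` from 1 to
0.35 and `s_b` from 0 to 0.6, which spans "bright, unshaded" to "dark with a
strong gradient" while keeping every image non-degenerate. Grade 1 is
exactly the identity.

**Noise.** `σ_n² = 125 (n − 1)`, so grade 1 adds nothing (and is
bit-identical to the shaded image on disk) and grade 14 has σ ≈ 40.3 gray
levels. Each grid cell (r, b, n) gets an independent, reproducible random
stream derived from the global seed via `SeedSequence([seed, r, b, n])`.

**Scene content.** Each scene holds flat-intensity objects of up to nine
shape classes (disc, square, rectangle, triangle, ellipse, annulus, cross,
L-shape, star) on a mid-gray background (110). The default family has
`14 + 2 (r − 1)` objects of `5 + ((r − 1) mod 5)` classes in scene `r`;
class `k` has base intensity `170 + 10 (k − 1)` with a per-object jitter of
±4 gray levels and a characteristic size of `0.15 · min(m, n) ·
sqrt(14 / n_objects)` with ±20% jitter, so every scene covers roughly 12% of
the image. That coverage is deliberate: with foreground below the upper
normalization quantile (2% of pixels), quantile normalization and Otsu
thresholding operate on background noise alone and every pipeline fails even
undistorted, which would make the benchmark uninformative. Placement is
rejection sampling with a clearance of `0.75 · size + 2 px` between object
centers — `0.75 · size` bounds the circumradius of every shape, so objects
never overlap and keep a ≥ 2 px margin, and instance ground truth is
unambiguous. Objects never touch the border (the reference pipeline clears
border components). Ground-truth files are written as
`benchdata_rr_truth.tif` (8-bit class labels), `benchdata_rr_instances.tif`
(16-bit instance ids) and `benchdata_rr_objects.csv`; this naming is this
package's convention.

## Artifact level

Both distortion axes are mapped to `[0, 1]` by the cubic smoothstep
`μ(x) = 3t² − 2t³`, `t = clip((x − α)/(β − α), 0, 1)` — the simplest
monotone spline that saturates below α and above β. Defaults:

* shading: bounds on the image mean, α = 40, β = 140, scored as
  `1 − μ(mean)`. The band brackets the default scenes' sweep (mean ≈ 128
  unshaded, ≈ 30 at grade 13); images brighter than 140 count as unshaded,
  darker than 40 as fully shaded. Both bounds are user-tunable.
* noise: bounds on σ, α = 0, β = `sqrt(125 · 13)` ≈ 40.3 (the top of the
  default schedule). For benchmark images the true σ_n from the manifest is
  used; for foreign images σ is estimated from the median absolute deviation
  of a second-difference (Immerkær) residual, which is insensitive to
  offsets and smooth gradients.

The artifact level `A` is the arithmetic mean of the two memberships
(configurable to `max`). Along the default diagonal series A is
monotonically non-decreasing.

## Quality and robustness

Detections are matched to truth objects one-to-one, greedily by descending
pixel overlap with deterministic id-based tie-breaks; any positive overlap
qualifies (no IoU gate). `m1`, `m2`, `m3` are defined in the README; all are
clipped to `[0, 1]` and each can be replaced or re-fuzzified via
configuration. Defaults: identity fuzzification and equal weights (⅓, ⅓, ⅓),
so `Q` stays interpretable as a plain mean. False-positive detections lower
`m1` and `m2` but not `m3`. Evaluating ground truth against itself gives
`m1 = m2 = m3 = Q = 1` exactly.

`R` is the mean of `Q` over the diagonal series `(b, n) = (k, k+1)`,
`k = 1..B`, consuming all 14 noise grades; it is order-invariant and bounded
by `[0, 1]`. The trapezoidal area under Q-vs-A, normalized by the A-range, is
offered as an alternative summary (it weights by artifact spacing instead of
grade count); a sigmoid-regression inflection-point summary is not
implemented.

## Reference pipeline

* Quantile normalization maps the 2%/98% percentiles to `[0, 255]` and
  clips. Degenerate case: if the two percentiles coincide (dominant constant
  background) the min/max range is used instead; a constant image maps to
  all zeros rather than erroring.
* Otsu threshold: exhaustive maximization of between-class variance over a
  256-bin histogram on `[0, 255]`; foreground is strictly above the
  threshold; ties take the lowest threshold. Constant images raise an error
  at the operation level; the pipeline treats them as "no foreground".
* Sobel segmentation: Otsu threshold on the gradient magnitude (computed on
  the gradient's own scale), two 3×3 dilations to close contours, hole
  filling, two erosions. This is a minimal standard recipe; its sensitivity
  to noise is part of what the benchmark is meant to expose.
* Postprocessing: hole filling, one 3×3 opening, border clearing, 8-connected
  labeling.
* Features: area, mean/max/min/median/std of intensity, solidity
  (area / convex hull area) and eccentricity (foci distance / major axis of
  the second-moment equivalent ellipse), via `skimage.measure.regionprops`.
* Classifier: Gaussian naive Bayes with empirical priors, per-class diagonal
  variances floored at `1e-6` of each feature's global variance, ties broken
  toward the smaller class id. It is trained per scene on the ground-truth
  instances of the clean image, with features extracted from the identically
  normalized image — training data and flavor are this package's choices.

## Numerical choices and degenerate inputs

* Rounding to 8 bit is half-up (`floor(x + 0.5)`), applied only at file
  write; in-memory evaluation quantizes the same way before scoring so disk
  and in-memory paths agree bit for bit.
* Zero-object scenes render and load fine; quality evaluation then refuses
  to score (`o_truth ≥ 1` is required).
* `robustness_auc` requires ≥ 2 points and a non-degenerate, duplicate-free
  A-range; `evaluate_series` simply omits the AUC when A values repeat.

## What the synthetic generator does and does not emulate

It reproduces the released data set's *structure*: the (r, b, n) grid and
naming, identical scene content across grades, 5–9 classes per scene with
pixel-level class and instance truth, 8-bit TIFF storage. It does not
attempt photorealism: objects are flat-intensity, non-overlapping and
axis-unaligned but unoccluded; there are no cast shadows, specular
highlights, texture, or the irregular silhouettes of real hardware items,
and shading is a smooth planar field rather than the field of two physical
lamps. Passing tests therefore demonstrate that the measures and harness
behave correctly and that the reference pipelines degrade plausibly under
graded distortion — not that any pipeline's absolute R value transfers to
photographed data. In particular the reference robustness values obtained
here (e.g. `R_otsu ≈ 0.29` vs `R_sobel ≈ 0.11` on scene 1 at 250×375, seed
42) characterize these synthetic conditions only.

## Problem sizes

The test suite and the worked examples render scenes at 250×375 (the same
6.25:1 aspect-preserving reduction of the 1000×1500 default); full-size
generation and evaluation use identical code paths and stay within a few
tens of seconds per pipeline sweep on one CPU.

## Known limitations

* Greedy overlap matching can differ from an optimal assignment when one
  detection straddles several truth objects; with non-overlapping truth
  objects this is rare and deterministic.
* `m3` ignores false-positive detections by design; a pipeline that invents
  objects is penalized via `m1`/`m2` only.
* No uncertainty quantification on R (e.g. bootstrap over scenes).
* The artifact bounds (α, β) are calibration constants; comparing A values
  across different bound settings is meaningless.
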
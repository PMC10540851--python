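# Methods

## Problem and model

A ventral actin stress fiber is anchored at a focal adhesion at both ends and
is under tension, so it is close to straight, with bounded curvature and a
length close to the distance between its anchors.  `sftrace` turns these
biological priors into a constrained maximum-intensity fit: every unordered
pair of same-cell FA centroids is a candidate anchor pair, and the reported
fiber for a pair is the member of an endpoint-constrained parabola family
with the highest penalized mean intensity on the preprocessed actin image.

### Curve family

Let the chord frame have one anchor at the origin and the other at (d, 0).
A second frame is rotated by the skew angle θ; in it the anchors sit at
(0, 0) and (d cos θ, −d sin θ).  With y = a x² + b x + c, fixing c = 0 and
solving the second endpoint gives b = −tan θ − a d cos θ, so the curve
interpolates both anchors for every (a, θ).  x is sampled uniformly on
[0, d cos θ] and the samples are rotated back by θ; a rigid transform then
maps the chord frame onto the actual anchor pixels.  Properties that shape
the implementation:

* only d enters the construction, so the fit is independent of the fiber's
  orientation in the image (the property that permits tracking one fiber
  over time in a moving cell);
* a = 0 reduces to the straight chord for every θ — the family is degenerate
  along that line, which is why ties are broken toward smaller |a| first and
  smaller |θ| second, and why the recovered θ of a nearly straight fiber is
  less determined than its a;
* |θ| is limited to π/2 − 0.05 rad to keep the rotated frame well
  conditioned.

Arc length is evaluated in closed form via the standard antiderivative
(u √(1+u²) + asinh u)/(4a) with u = 2ax + b.  That difference cancels
catastrophically as a → 0, so below |u₁ − u₀| < 10⁻⁶·(1 + |u₀| + |u₁|) the
implementation switches to the midpoint-slope value x₁ √(1 + (a x₁ + b)²),
whose error is O((2 a x₁)²) and negligible at the crossover.  Maximum
unsigned curvature |2a|/(1 + (2ax + b)²)^{3/2} is |2a| when the vertex lies
in the span, else the larger endpoint value.

### Penalty and score

For violation magnitude χ with threshold t and amplitude A, the penalty is
p = 1 for χ < t and p = exp(A (χ − t)) for χ ≥ t — continuous at t, equal to
one below it.  Three penalties are evaluated per candidate and accumulate by
multiplication (equivalently, exp of the summed excesses):

| violation χ            | threshold          | default |
|------------------------|--------------------|---------|
| chord overshoot (px)   | 0 (fixed)          | —       |
| relative length L/d    | `t_length`         | 1.3     |
| max curvature (1/px)   | `t_curv`           | 0.05    |

with shared amplitude `A = 50`.  The score is the arithmetic-mean intensity
along the placed curve (bilinear interpolation, out-of-bounds samples read
0, which self-penalizes wandering curves) divided by the penalty product.
The geometric mean is also reported but not optimized (config switch
`objective: geom` exists).  The overshoot threshold of zero encodes that a
fiber never extends beyond its own adhesions; a stricter interpretation —
discarding any overshooting curve outright — is available as
`penalty.reject_rewind` but is off by default, keeping the smooth
exponential form.

### Search

The fit is an exhaustive grid: 41 values of a spanning ±0.02 px⁻¹ scaled by
(100/d) — the sagitta of a parabola scales like a d², so scaling a's range
inversely with d keeps the explored shapes comparable across short and long
chords — and 21 values of θ spanning ±0.6 rad; curves are sampled at
max(64, ⌈2d⌉) points.  Grid search makes the optimizer trivially
deterministic and lets the test suite assert *exact* equivalence against an
independent scalar brute-force implementation (the batched arithmetic
mirrors the scalar path operation-for-operation).  Ties are broken by
smaller |a|, |θ|, a, θ in that order.

## Preprocessing

**Actin channel** — the preprocessed image is the unit-max-normalized sum of
the raw image, `w_contrast` times a percentile contrast stretch, and
`w_edge` times a binary Canny edge map.  The defaults are the control values
used throughout validation: stretch percentiles 10/50, Canny hysteresis
thresholds 0.005/0.3 (expressed as fractions of the maximum gradient
magnitude, hence applied to a normalized gradient), and weights 3:1.  These
percentiles deliberately saturate everything above the median intensity;
the benefit is that dim fibers near bright ones remain detectable.
The corresponding cost is a compressed score scale — any within-cell chord
picks up the saturated cytoplasm — which is why the acceptance threshold
sits high (below).

**FA channel** — median filter (disk, radius 2 px) against shot noise, then
white top-hat (disk, radius 15 px) to remove the diffuse signal of soluble
vinculin, then Otsu thresholding inside the cell mask and an area gate of
[20, 3000] px².  Shape descriptors use the equivalent-ellipse (second
central moment) convention; orientations are degrees in (−90, 90] from the
+x axis, positive toward +y (y down) — stated explicitly because "orientation"
alone is convention-dependent.

**Cell mask** — both channels are normalized to unit maximum, summed, and
renormalized; grayscale dilation (disk, 4 px) and Gaussian smoothing
(σ = 6 px) close the gaps between fibers and adhesions so one cell becomes
one 8-connected component; Otsu binarization, a 2000 px² size filter and a
border check follow.  Defaults are sized for 2048×2048 frames and are all
config-exposed.

## Acceptance threshold

`fit.accept_threshold = 0.80` (preprocessed-intensity scale) was calibrated
once on the bundled default scene: with the control preprocessing above,
true anchored strokes score 0.83–0.86 while the best spurious pair reaches
0.75, so 0.80 sits in the gap.  This mirrors the intended workflow on real
data — the threshold is a per-dataset user setting (and should be re-tuned,
e.g., when noise raises the overall intensity level); it is not a universal
constant.  The number of reported fibers is the quantity most sensitive to
it, which the preprocessing sweep harness makes easy to visualize.

## Synthetic scenes

`synth` renders what the pipeline consumes: an FA plane with
Gaussian-profile elliptical puncta (major/minor given as FWHM) and an actin
plane with fiber strokes stamped as Gaussian cross-profiles (FWHM =
`width_px`, σ = FWHM/2.355, approximating diffraction-limited fibers) along
polylines generated by the *same* curve-family code the fitter searches —
so the analytic descriptors of a truth stroke are exactly those of a
perfectly recovered curve.  Stroke ridges are rasterized at 4 samples/px and
distances come from a Euclidean distance transform; the ≤0.5 px raster error
is far below the profile widths used.  Strokes may share anchor blobs;
distractor strokes have free endpoints and model fibers that do not start
and end at adhesions — a correct analysis must not report them.

Scenes carry an elliptical **cell body**: cytoplasmic base intensity 0.12
inside, modulated by a deterministic sinusoidal texture (amplitude 50%,
periods ≈ 250 px, emulating uneven illumination; deliberately not random so
renders are bit-reproducible), over a dark exterior.  This serves three
purposes: the composite is maskable into a single cell, the percentile
contrast stretch is well defined (a constant background makes P10 = P50
degenerate), and within-cell chords see realistic cytoplasmic signal, which
is precisely what makes false-positive control non-trivial.  The texture
period sits far above the FA top-hat scale on purpose: preprocessing must
remove it as it removes diffuse vinculin.

The default validation scene is 2048×2048 with 8 blobs, 5 anchored strokes
(a mix of straight and curved, skewed members, curvatures within the default
search range), and 2 distractors.  Stroke geometry avoids near-collinear
triples of adhesions: where two strokes share a blob they meet at a wide
angle, otherwise a low-curvature parabola between a *non*-anchored pair
could ride two collinear fibers and scored as a false positive — on real
images such a configuration is genuinely ambiguous even for a human
annotator.  A compact 512² two-stroke scene with the same structure backs
the fast tests.

What passing on these scenes does **not** show: robustness to fiber
crossings at shallow angles, photobleaching gradients, out-of-focus apical
signal, or textured cytoplasmic actin — real micrographs are harder, which
is why the interactive drop-list (`evaluate.filter_curves`) exists.

## Robustness harnesses

`run_corruption_sweep` re-runs the full pipeline per condition: additive
Poisson noise on the actin channel (counts added on the source bit-depth
scale, then clipped and renormalized — the acceptance threshold is *not*
auto-adjusted, so fiber counts rise with λ), block-mean downsampling
(applied to both channels, since acquisition resolution affects the whole
field; all pixel-unit parameters are rescaled via `downsample_config` — 
lengths by 1/f, areas by 1/f² — so the analysis is identical in physical
units), and requantization (round-to-nearest on [0, 1]; 6-bit emulates a
reduced dynamic range).  `run_preprocess_sweep` varies only the
SF-preprocessing parameters.  Both are deterministic given a seed.

## Numerical and interface conventions

* Coordinates are (x, y) = (column, row), 0-based, pixel centers at integer
  coordinates, y increasing downward; every exported centroid and polyline
  uses this convention.
* Intensities are float64 in [0, 1]; ingest divides by the bit-depth
  maximum (255 for 8-bit).
* Poisson corruption is additive with mean λ counts (an offset-like noise
  floor), not signal-dependent shot noise.
* Equivalent-ellipse minor axes are floored at 10⁻³ px so one-pixel-thin
  regions keep a finite aspect ratio.
* Blank or unsegmentable inputs yield empty result tables and exit code 0,
  not an error.
* All randomness (only the Poisson corruption, by default) flows through an
  explicit integer seed; fixed inputs + config + seed reproduce every output
  byte-for-byte.

## Problem sizes

The default full-scale validation (2048², 8 FAs → 28 pairs, 41×21 grid,
up to ~2800 samples per curve) completes in well under a minute on one CPU;
the test suite leans on the 512² scene for everything that does not
specifically require full scale.

## Known limitations

* One curve per FA pair: parallel fibers between the same two adhesions are
  not representable.
* No dorsal-fiber/transverse-arc classification, no fiber width, no
  temporal tracking (the orientation-stable parametrization is designed to
  enable it later).
* Touching cells are not separated (no watershed); the masking stage
  assumes analyzable cells do not touch.
* The FA preprocessing (median + top-hat + Otsu) is a documented,
  config-exposed pipeline validated against synthetic ground truth; labs
  with different FA stains may need different radii or thresholds.
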
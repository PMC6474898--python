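# Methods

`fadseed` implements the analysis chain used to test **fitness-associated
dispersal (FAD)** in *Lamium amplexicaule*: whether low-fitness plants
produce seeds that are more attractive to their ant dispersers.  The seed
phenotype at the center of the chain is *percent spot cover* — the
fraction of the seed-coat area occupied by dark pigmentation spots.  This
note records the models, the defaults, and the design choices that were
genuinely open.

## Seed image segmentation

A seed photograph is decomposed into three binary layers:

1. **Seed body.** Grayscale (luma) Otsu thresholding separates the dark
   seed from a pale background, followed by binary opening and closing
   (disk radius 2 px, configurable) and selection of the largest
   8-connected component at or above 0.5% of the image area (the minimum
   rejects dust; a scene with two such components is an error, not a
   guess).  Holes are filled.
2. **Spots.** A second Otsu threshold computed over seed-body pixels only.
   Otsu always returns a split, even on an unspotted coat, so the split is
   accepted only when the dark/light class means differ by at least
   `min_spot_contrast` (default 25 gray levels); otherwise the spot layer
   is empty.  This guard is what makes the zero-cover case well-posed.
3. **Elaiosome.** The elaiosome is pale and lipid-yellow, so its pixels
   are near-background in luma but hue-shifted: the gate keeps pixels with
   `(R+G)/2 − B > 35` and brightness > 175 outside the seed body, opens
   them with a 1-px disk, and retains the largest component adjacent to
   (within 3 dilations of) the seed boundary.

Spot cover is `100 · |spots| / |seed body|`; the denominator excludes the
elaiosome, a deliberate convention — spot cover is a property of the seed
coat, and the elaiosome is measured as its own layer.  Areas are reported
in pixels, or multiplied by `scale²` when a physical scale (length per
pixel) is supplied.  Coordinates are row-major, origin top-left, 0-based;
bounding boxes half-open.

The tool assumes one seed per frame against a contrasting background, as
produced by a USB microscope rig.  It does not attempt multi-seed scene
parsing, color calibration across devices, or shape descriptors beyond
area/centroid/bounding box.

## Synthetic data

The study's raw images and logs are not public, so the package generates
all inputs with known ground truth.

**Seed images.** An ellipse (default semi-axes 80 × 55 px in a 256 × 256
frame) on a neutral background (gray 205), seed coat RGB (140, 110, 85),
spots (60, 40, 30), elaiosome (235, 225, 150) as a disk at one pole of
the major axis.  Spot texture is a Gaussian-smoothed noise field
(blob diameter ≈ 9 px) thresholded at the *empirical quantile* that
realizes the target cover, so the truth masks are exact by construction
(within pixel rounding, guaranteed ≤ 1 percentage point).  Additive
Gaussian pixel noise (s.d. 6 of 255) is applied last.  These shades make
intensity-based segmentation well-posed — which is the point of the
fixture — but they also make it *easier* than real micrographs:
there is no shading gradient, no specular highlight, no partial focus,
and the spot/coat contrast is fixed.  Segmentation accuracy measured on
these images is an upper bound on real-image accuracy, and the recovery
tests should be read as validating the algorithm's correctness, not its
field robustness.

**Plant population.** 30 plants; whorl count uniform on 12–20; flowers
per whorl Poisson(8); the fitness proxy is the flower total excluding the
top whorl (≈ 120 on average, s.d. ≈ 23 across plants).  Mean seed cover
follows `18 + 0.078 · total_flowers` percent with plant-level noise
s.d. 3.2 and within-plant seed noise s.d. 6, clipped to [0, 100].  One
seed per whorl is sampled (≈ 480 seeds per 30-plant sample).  These
defaults reproduce the observed scale of the system — seed covers
spanning roughly 15–45%, a weak but detectable plant-level association
(R² ≈ 0.2) — with the slope and sample sizes taken from the study design;
the flower and whorl distributions are not reported anywhere and are this
package's choices, exposed as parameters.  Elaiosome area rises mildly
with flower count (900 + 2 px/flower, s.d. 60), matching the direction of
the reported elaiosome–fitness association.

**Germination.** Bernoulli germination per category (defaults 0.74
unspotted, 0.898 spotted, 108 seeds each), day-of-event normal (unspotted:
mean 9 d, s.d. 4; spotted: mean 7 d, s.d. 1.8 — the unspotted category is
both less likely to germinate and more variable in timing), rounded to
whole days, censored at a 30-day horizon.  The study horizon is not
reported; 30 days comfortably exceeds both time distributions.

**Assay logs.** Paired trials: 212 trials over 3 sessions; the unspotted
seed is removed with base probability 129/212, shifted per session on the
logit scale (s.d. 0.3).  Grid: an even-sided checkerboard (8 × 8); at
each step the removal is drawn from the remaining unspotted seeds with
probability `grid_preference` (default 0.75), otherwise from the spotted;
an exhausted category forfeits its draws.  The parameter is a
*probability*, not an odds: 0.5 is the blind-removal null and 1.0 removes
every unspotted seed first.  Ant movement is not simulated, only removal
outcomes.

All generators are pure functions of their parameter objects (including
the RNG seed), and truth labels are carried explicitly — downstream
quantile classification never defines them.

## Phenotyping

The fitness proxy omits the top whorl (its development is partial); a
single-whorl plant therefore has fitness 0, which is logged rather than
rejected.  Seed categories are **rank-based**: exactly `floor(0.15·n)`
lowest covers are "unspotted" and `floor(0.15·n)` highest "spotted"
(72 + 72 at n = 486).  Floor rounding guarantees the tails never overlap;
ties spanning a cut are broken by stable input order and logged; an
all-equal distribution is an error, never silently labelled.  Whether the
original 15% cut was applied per light regime or pooled is unknown; the
pipeline classifies per dataset and the caller may pool or split.
Plant-level variance of cover uses the unbiased n−1 estimator and is
*missing* (not 0) for single-seed plants.

## Statistics

* **Plant-level association**: OLS of mean cover (y) on total flowers
  (x), slope t-test with n−2 df.  The regression direction matches the
  figure axes of the source design; the caller can swap.
* **Seed-level association**: linear mixed model with a per-plant random
  intercept, REML (the estimation method is not reported in the source;
  REML is the conventional default and is recorded in the fit metadata).
  Degenerate cases reduce to pooled OLS: a single group (with a warning)
  or data the pooled line fits exactly, where REML's variance components
  are unidentified.
* **Rank-sum test** (shared by germination, regime comparisons, and the
  grid assay): the statistic is the Mann–Whitney U of the first sample
  computed from midranks.  For combined n ≤ 12 the p-value is exact by
  full enumeration of the C(n, n₁) group assignments (two-sided = twice
  the smaller tail including the observed point, capped at 1); otherwise
  the normal approximation with tie-corrected variance and a 0.5
  continuity correction.  The response may be a germination time, a
  binary outcome, or a removal rank — the test is generic over any
  numeric response, since the source applies it to more than one.
* **Inverse Kaplan-Meier**: 1 − the product-limit survival estimate;
  non-germinators are right-censored at the horizon.  Without censoring
  the curve equals the empirical CDF exactly (property-tested).
* **Log-rank test**: standard observed-minus-expected χ² with 1 df for
  two groups.  It is reported as what it is — a test of distribution
  difference over time — with descriptive variances computed separately,
  not as a variance test.
* **Paired-trial preference**: removals per category divided by total
  trials; two-sided exact binomial sign test against 0.5; raw odds ratio
  = spotted/unspotted removals.  The published OR (0.391) came from a
  mixed model over session structure that cannot be reconstructed from
  the printed totals, so the raw OR and the sign test are the
  reproducible estimators.
* **Mixed logistic model**: intercept-only logistic GLMM on the outcome
  "spotted removed" with a Gaussian random intercept per time point,
  fitted by maximum likelihood with 25-node Gauss–Hermite quadrature and
  Nelder–Mead over (β, log σ), multistarted over the variance scale.
  This is hand-written because the per-group data collapse to binomial
  counts, making the one-dimensional quadrature exact to machine noise
  and fast; with zero between-time variance the OR reduces to the raw
  odds ratio.  Complete separation raises an explicit error.  "Time
  point" granularity defaults to one level per distinct time stamp, with
  optional equal-width binning.
* **Blind-removal null** for the grid: hypergeometric upper tail of the
  focal-category count among k category-blind draws.

Two-sided p-values throughout; no multiple-testing correction (none is
applied in the source design).  Unremoved grid seeds are excluded from
the rank test (the analysed logs are completed removal sequences); a
censored-rank variant is out of scope.

## Reconstructed assay logs

`fadseed.fixtures` rebuilds the two desk-reproducible inputs from printed
totals: a 212-trial log with 129 unspotted / 83 spotted removals split
into the published session sizes, and an 8 × 8 grid log whose first 32
removals take 24 unspotted and 8 spotted seeds.  Only the totals are
published, so the within-log order is a deterministic even interleaving —
these are synthetic stand-ins sufficient for the order-insensitive
statistics (fractions, half-removal state), not the historical sequences.

## Problem sizes and numerical choices

Simulation-based validation uses: 50 images across covers 5–45% for
segmentation recovery; 500 replicate populations (30 plants each) for
slope coverage; 200 replicates of 200 trials × 20 sessions for the GLMM
odds-ratio recovery; 2 000 null replicates for the size of the sign and
slope tests; 2 000 label permutations for log-rank calibration.  These
sizes give Monte-Carlo standard errors comfortably below the asserted
margins while keeping the full suite in the low minutes.

Tie-breaks and degenerate inputs are handled explicitly everywhere they
can arise: Otsu on an unspotted coat (contrast guard), all-equal cover
distributions (error), single-seed variance (missing), single-group mixed
models (OLS fallback with warning), all-one-category removal logs
(separation error), empty masks (error on measurement, identity on
rendering).

## Known limitations

* The synthetic images are idealized (see above); no claim is made about
  segmentation accuracy on real micrographs.
* Seed "estimated weight" is not computed — no formula for it exists in
  the source — and the output schema flags it as absent.
* The mixed logistic model is intercept-only, matching the assay design;
  covariates would require extending the quadrature likelihood.
* The rank test on grids ignores never-removed seeds; runs stopped before
  clearing the board lose information.
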
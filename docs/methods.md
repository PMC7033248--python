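# Methods

This note documents the models, conventions and numerical choices
behind `adenoquant`, and what the synthetic data do and do not show.

## Segmentation

The pipeline assumes photographs of opened small-intestine tissue
spread on blue card, 8-bit RGB, with a known physical scale
(mm per pixel side) supplied explicitly or derived from a two-point
ruler annotation (`scale_from_two_points`); automatic ruler detection
is out of scope and the scale is never guessed.

**Background subtraction.** Each pixel is scored by blueness
`b = B − max(R, G)`. Card pixels score high (the card is chosen for
contrast with tissue); tissue, lesions, fat and reflections score near
or below zero. The background cut on `b` is the Otsu threshold of the
blueness histogram, *except* when the lower Otsu class still has
card-like mean blueness (above the fixed floor of 25): that happens
exactly when tissue is sparse or absent and Otsu has split the card's
own noise, and the cut then falls back to the floor. The floor sits
roughly five noise standard deviations below the card's typical
blueness (≈ 60 for the reference card colour) and at least twenty
above any tissue-like colour, so it is insensitive to moderate
lighting changes. Non-background pixels become 8-bit luma
(0.299 R + 0.587 G + 0.114 B); a lesion-free frame yields an all-zero
grey image.

**Thresholding** is iterative intermeans on the 8-bit histogram
(initialise at the overall mean, iterate `t ← (mean_below + mean_above)/2`
to a fixed point; foreground is `> t`), with Otsu as a configurable
alternative. **Despeckling** is a 3×3 binary median filter (radius
configurable). Components are 8-connected (configurable), holes are
filled before measurement by default (lesion interiors can threshold
unevenly), and automatic features must have physical area ≥ 0.2 mm².
Manual (DRAW) masks skip the area filter: hand delineations are
authoritative.

## Morphometry

Pixels are unit squares. Convex-hull geometry (Feret, MinFeret,
FeretAngle, Solidity) uses the four corner points of every member
pixel, so a single pixel has Feret √2 and MinFeret 1. Maximum Feret is
the largest hull-vertex pair distance; minimum Feret is the smallest
width normal to a hull edge (rotating calipers). The fitted ellipse
matches the region's second central moments (each pixel contributing
the 1/12 moment of a unit square) and is rescaled to have exactly the
region's area; angles are degrees in [0, 180), counter-clockwise from
the x-axis with y up. Intensity moments use population normalisation;
kurtosis is excess; mode ties break toward the smaller intensity.

Perimeter defaults to the 4-direction Crofton estimate rather than the
raw 8-connected chain code: the unsmoothed chain code overestimates
smooth boundaries by ~5%, which drives the circularity of a digitised
disk down to ≈ 0.91, whereas Crofton gives ≈ 0.996. Chain-code
(√2-weighted) remains available as `perimeter_method="chain-code"`.
Circularity is capped at 1.

Two measures are exactly dependent by construction: `IntDen =
Area·Mean` and `RawIntDen = IntDen / scale²`. This matters downstream
(see regularization).

## Preprocessing

Discriminant analysis dislikes heavy tails and outliers, so each
measure passes through a per-measure rule: log10 for the strictly
positive size measures (Area, Perim, Major, Minor, Feret, MinFeret,
IntDen, RawIntDen); shifted log10 (`log10(x + c)`, c = 1 − training
minimum) for the signed moments Skew and Kurt; drop for Angle and
FeretAngle (orientation reflects how the tissue was laid out, not what
the feature is); identity otherwise. Optional validity intervals mark
out-of-range values missing; any non-finite transform result is
missing; rows with a missing retained value are removed (NA-called
features are always excluded from training). The retained columns are
then augmented with their squares — originals first, then squares — so
a linear boundary in the augmented space is a conic in the original
one. The spec is serialized (JSON, hashed) and must be reused verbatim
when scoring new tables: the offsets are training-set quantities.

## Discriminant

Classical two-class LDA: class means, pooled within-class covariance
(denominator N − 2), empirical priors, plug-in posteriors. A feature
is called Ad when its Ad posterior exceeds 0.5; an exact tie goes to
nAd (conservative). Because log IntDen and log RawIntDen differ by a
constant, the pooled covariance of a measured table is always
singular; the fit therefore adds a per-column ridge of 1e-6 times each
diagonal entry whenever the Cholesky factorisation fails or the
condition number exceeds 1e12. The ridge is scale-aware on purpose:
the 40-odd columns span ~6 orders of magnitude, and a uniform ridge of
comparable total size measurably degrades accuracy by drowning the
low-variance shape measures. Null directions introduced by the exact
collinearities carry zero between-class mean difference, so the ridge
does not distort the discriminant.

## PCA quality control

Features are nested in mice, and a single poorly photographed mouse
can bias every one of its features. The QC standardises the design
matrix (correlation PCA), takes each mouse's barycentre on PC1–PC2,
scales it by √(number of features) — a barycentre of n features has
sampling variance ∝ 1/n, and without this scaling the false flags
concentrate on low-count mice — and computes robust squared
Mahalanobis distances via the minimum covariance determinant (MCD),
median-rescaled to the chi²(2) median (the usual MCD consistency
correction).

The flag cutoff is family-wise rather than per-mouse: the question
"does this cohort contain a biased mouse?" is asked once across all
mice, and a per-mouse 1% rule would flag ≈ 0.5 innocent mice per
50-mouse cohort (more in practice, since MCD distance tails are
heavier than chi²). Instead the cutoff is the 95% quantile of the
*maximum* distance observed in simulated bias-free cohorts of the same
size (standard-normal barycentres; valid for any Gaussian null because
MCD distances are affine-invariant; 200 simulations, cached per cohort
size, internally seeded and deterministic). An unbiased cohort then
flags anything in ~5% of realizations, while a +3 SD batch shift on
six measures produces distances two orders of magnitude above the
cutoff. `family_alpha` is configurable.

## Bootstrap validation

`sample_dataset` draws mice uniformly with replacement — a mouse drawn
twice contributes its features twice, the standard bootstrap
semantics — stopping at the first point where draws ≥ 12 *and*
accumulated features ≥ 750; candidates with under 30% of either class
are rejected wholesale and redrawn (rejections are not counted toward
the dataset total; a cap of 10 000 rejections guards against
unsatisfiable tables). Each of the 4000 accepted datasets trains its
own discriminant and is scored in-sample, matching how the validation
experiment is defined; an out-of-bag mode (score on never-drawn mice)
exists but is off by default. Quantiles use linear ("type 7")
interpolation. Everything is reproducible from the single seed.

Indicator conventions: ACC, per-class TPR and PPV from the 2×2
confusion counts; `Ad_ratio` = predicted Ad over true Ad (identically
`TPR_Ad / PPV_Ad` when the latter is defined) and `nAd_ratio`
analogously. Undefined indicators (a class absent) are reported as NaN
with a warning, not silently dropped. A ratio of 1 does not imply
perfect classification — equal numbers of false positives and false
negatives also give 1.

## Method comparison

Mouse-level burden (Ad count, total Ad area; DRAW counts every
delineated feature, CALL counts manual Ad calls, LDA counts predicted
Ad) is compared with Deming regression at variance ratio 1, i.e.
orthogonal regression: slope
`[(Syy − Sxx) + √((Syy − Sxx)² + 4Sxy²)] / (2Sxy)`. Confidence
intervals are BCa bootstrap over mice (n = 999, seeded): the bias
correction comes from the resample distribution, the acceleration from
a jackknife over mice. BCa is implemented in-package rather than via a
library call so that degenerate resamples (Sxy = 0) can be redrawn
(capped at 10× n_boot) and exactly collinear inputs get a zero-width
interval instead of an undefined one. Mann-Whitney U (asymptotic, tie
corrected) and Kruskal-Wallis are exposed as thin reporting wrappers
around scipy.

## Synthetic data

`generate_image` emulates the photographic setup: noisy blue card
(RGB ≈ (70, 110, 170), σ = 5), sessile elliptical lesions with
intensity falling off as `exp(−ln2·u^6)` in elliptical radius u —
half-intensity exactly at the true boundary, so a threshold at
half-height recovers the analytic area — aspect ratios 1–1.6, centres
≥ 3 mm apart, plus optional distractors: thin high-aspect streaks
(rolled edges), pale yellow fat patches and small bright reflections.
Ground truth records every lesion's pixel set and analytic area;
distractors are recorded separately. It does not model tissue texture,
vignetting, stitching seams or uneven lighting, so segmentation tests
show correctness of the pipeline's logic, not its robustness to every
real-world artifact.

`generate_table` emulates the verified feature table of a 117-mouse
study: Poisson(27.25) features per mouse, 40.1% Ad, class signal in
eight informative measures (Ad larger, rounder, brighter, more solid;
nAd more elongated with heavier intensity tails) and all derived
measures filled in coherently (exact ellipse geometry, Perim from
Circ and Area, IntDen = Area·Mean, …) so generated tables satisfy the
same invariants as measured ones. The class-mean gap
(`class_separation`, default 0.58) was fixed once so that a
full-dataset fit sits at the working point expected of this pipeline
on verified data (ACC ≈ 0.87–0.88, Ad TPR ≈ 0.82, nAd TPR ≈ 0.92,
Ad_ratio ≈ 0.94). Per-mouse random effects (default SD 0.1 latent
units) add mild mouse-level correlation; chosen mice can receive an
injected batch bias (default +3 SD on six measures) for QC tests; a
radial mode places concentric class geometry in the (Mean, StdDev)
plane to exercise the quadratic augmentation. Because the generator is
multivariate-Gaussian in latent space, classifier results on it show
algorithmic correctness at a realistic working point, not performance
on real photographs.

## Problem sizes and determinism

The test suite runs the bootstrap at 200 datasets on reduced tables
and the Deming coverage simulation at 500 replicates with 199–299
bootstrap resamples; `scripts/acceptance.py` runs the full 4000-dataset
bootstrap on the full 117-mouse table, 999 Deming resamples, and 1000
resampling-contract checks. Every stochastic component takes an
explicit seed; reruns are bit-identical.
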
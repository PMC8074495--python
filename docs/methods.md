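# Methods

`fundusrad` re-implements a radiomics analysis of the optic-disc region in
color fundus photographs for severe myopic maculopathy (MM): high-throughput
feature extraction from manually annotated regions of interest, a
filter-plus-wrapper feature-mining cascade, and an evaluation battery.
This note records the model assumptions, the numerical choices made where
the design was genuinely open, and what the synthetic phantoms do and do
not establish.

## Regions of interest and geometry

Each eye contributes three annotations: the optic-disc boundary, the outer
boundary of the peripapillary atrophy (PPA) crescent, and the macula
center.  Coordinates are 0-based with `x` = column, `y` = row, `y`
increasing downward; a pixel `(row, col)` has center `(col + 0.5, row +
0.5)` and belongs to a region iff its center lies inside the polygon.
Hand-drawn contours are smoothed with a **zero-smoothing periodic cubic
B-spline** (interpolating, resampled at 4x the input density by default).
Interpolating splines overshoot sharp corners — a square traced by corners
and edge midpoints gains a reproducible 6.7 % of area — which is acceptable
here because anatomical boundaries are smooth; the enclosed area of convex,
smoothly sampled contours (>= 12-16 points) changes by well under 5 %.

The PPA region is the fill of the outer contour minus the fill of the disc
contour; the two masks are disjoint by construction and this is asserted in
the `RoiSet` constructor.  Left eyes are mirrored to right-eye orientation
before extraction (`x -> (W-1) - x` for annotations, column reversal for
rasters), so nasal/temporal asymmetries are comparable across eyes.

## Feature pool (322 columns)

The selection universe has 316 automatic features — 151 morphologic, 54
intensity, 111 texture — plus the six *clinic* features re-emitted under
their clinical names (AreaPPA, AreaDisc, Tilt, Torsion, Dist_MD, Angle_MD).
The published total fixes the counts but not the rosters, so the exact
rosters below are a contract of this package:

* **Morphologic (151)** — clinic-feature ingredients (areas, disc axes and
  orientation, macula offset: 10, emitted with a `shape_` prefix to keep
  names unique); 16-station curvature profiles of both contours with
  mean/SD/max (38), computed from spline derivatives with station 1 at the
  temporal-most point; region properties (perimeter, area/perimeter,
  circularity, solidity, extent, eccentricity, convex area) for disc and
  PPA (14); central moments, normalized moments and Hu invariants per
  region (42); elliptic-Fourier magnitudes `|c_k|/|c_1|` for k = 1..10 and
  Fourier circularity per contour (22); inter-contour nearest-point
  distances (Hausdorff, mean, min, median — the max of pooled nearest
  distances *is* the Hausdorff distance, hence the median instead) (4);
  radial PPA width statistics over 72 rays (5); the PPAweight family (9);
  and seven derived area/length ratios.
* **Intensity (54)** — the 18 standard first-order statistics on the PPA
  region of each RGB channel.  Entropy (bits) and uniformity use the same
  32-level equal-width quantization as the texture features; variance,
  skewness and kurtosis are population moments, kurtosis non-excess;
  a constant region has skewness = kurtosis = 0 by convention.
* **Texture (111)** — per channel: 8 GLCM statistics (contrast,
  dissimilarity, homogeneity, ASM, entropy, correlation, cluster shade,
  cluster prominence) at 4 angles (0/45/90/135 deg, distance 1, symmetric,
  restricted to in-mask pairs, kept per angle because angle-specific
  features are of interest) and 5 NGTDM statistics (coarseness, contrast,
  busyness, complexity, strength; 8-neighborhood restricted to in-mask
  neighbors).  Coarseness is `1/(1e-6 + sum p_i s_i)` capped at 1e6 so the
  constant-region case is finite.  A GLCM correlation with zero marginal
  variance is defined as 1.

**PPAweight** (the radial-fluctuation operator): 72 rays are cast from the
disc centroid; along each ray's intersection with the PPA mask the channel
intensity is sampled at `u` equally spaced stations (bilinear), and the
feature is the mean over rays of the mean absolute successive difference.
It is zero for a constant region, linear in intensity scale, and grows as
the texture decorrelates radially.  This operator and the curvature-station
convention are documented stand-ins chosen for qualitative behavior; no
published formula pins them down.

Quantization uses a **fixed bin count of 32** equal-width bins over the
in-ROI intensity range (self-contained and deterministic; a constant ROI
collapses to one level).

## Mining cascade

Defaults reproduce the study settings: features are z-scored with
training-split statistics only (population SD; zero-variance features map
to 0 and are flagged); a plug-in mutual-information filter (10
equal-frequency bins, bits, threshold 0.2) and a pooled two-sample t-test
(two-sided, alpha 0.05) are intersected; Sequential Floating Forward
Selection then maximizes mean ROC AUC of a random-forest classifier under
stratified 5-fold CV (max cardinality 30), with ties broken by column
order.  The final cardinality is the smallest k that no larger k improves
by more than `tol = 0.005` (rise-plateau rule), and the decision model is a
100-tree random forest.  One seed governs the split, folds, bootstrap draws
and tree randomness; identical inputs give identical traces.

The wrapper criterion uses an internal bagged-decision-tree random forest
(bootstrap via multinomial sample weights, `max_features="sqrt"`) rather
than the heavier general-purpose estimator, because the wrapper evaluates
hundreds of candidate subsets; the public decision model is the standard
100-tree random forest.

For degenerate t-test columns (zero pooled variance) the p-value is defined
as 0 when the class means differ and 1 when they are equal.  The MI
estimator is positively biased at small n (plug-in bias ~ (bins-1)/(2N ln2)
bits), which makes the 0.2-bit threshold conservative on small cohorts.

## Evaluation battery

Severity follows the META-PM grouping: MDCA, C3, C4 or any plus lesion =
severe; C0, C1, PDCA = without.  The 70/30 split is severity-stratified
with validation = ceil(0.3 n).  Set-level AUCs are reported on the
validation split for the selected ("new") set, the six clinic features, and
their union.  Univariate feature performance is the mean +/- SD over
stratified 5-fold CV of a single-covariate logistic regression (the SD is
the fold SD).  Correlation between new and clinic features uses Pearson r
with two-sided p from the t transform (stars at 0.05/0.01/0.001;
zero-variance columns report r = 0).  Subclass profiles report mean +/- SD
per grade C0..C4 for features whose univariate AUC exceeds 0.75, with
adjacent grades compared by Welch's t-test and transitions flagged at
p < 0.01.  Percentages round half-up to one decimal.

## Synthetic phantoms

The phantom renders, at 256 x 256 px (a deliberate down-scale of the
2032 x 1934 source format; all geometry is proportional), a tessellated
fundus background, a bright elliptical disc (semi-major ~ 21 px, tilt
~ N(0.72, 0.08), near-vertical axis), a temporal-heavy PPA crescent, and a
dark macula spot ~ 85 px temporal to the disc.  Four per-eye latent drivers
carry the class signal, each with a 6-grade schedule whose two largest
jumps sit at C0->C1 and PDCA->MDCA and independent per-eye jitter:

| driver | controls | schedule (C0..C4) | jitter SD |
|---|---|---|---|
| PPA outer offset | AreaPPA and width features | 0.16..0.45 (rel. radius) | 0.10 |
| PPA brightness | first-order location stats | 14..38 (intensity) | 9 |
| blotch coverage | histogram complexity (entropy) | 0.05..0.35 | 0.06 |
| texture corr. length | NGTDM coarseness (severe = shorter) | 3.0..1.75 px | 0.5 |

Jitters were sized analytically so each driver alone separates the severity
groups at a standardized shift of roughly 1.2-1.5 (univariate AUC ~ 0.8;
measured on a 200-eye pilot: 0.81 / 0.80 / 0.73 / 0.93).  Because no single
feature saturates the classifier, the wrapper is rewarded for combining
drivers across feature categories.  The blotch field is mean-compensated so
heterogeneity does not confound brightness, and boundary wobble is demeaned
so the measured disc area recovers the analytic pi*a*b within 2 %.
Texture is a Gaussian random field (Gaussian-kernel-smoothed white noise),
giving monotone control of NGTDM coarseness through the correlation length.

What passing tests on phantoms do **not** show: the phantoms have no
vessels, no optic-cup structure, no illumination gradients or acquisition
artifacts, and their class-conditional distributions are Gaussian by
construction.  Recovery of planted effects demonstrates that the cascade is
implemented correctly and has the statistical power claimed at these effect
sizes — not that the same features would be selected on clinical data.

## Problem sizes used by the test suite

The default parameters are the study settings (wrapper forest 100 trees,
max_k 30).  The recovery checks run at desk scale: 300-eye cohorts,
wrapper forests of 20-30 trees and max_k 3-8, 10 master seeds for the
image-based cascade and 20 for the tabular one.  At these sizes the full
suite runs in roughly 20 minutes on one CPU.

## Known limitations

* The exact rosters behind the published 151/54/111 counts are not
  recoverable; only the totals and a handful of named features are pinned.
* The PPAweight and curvature-station constructions are plausible,
  documented operators, not reverse-engineered ones.
* NGTDM coarseness is strongly region-size dependent, so it tracks PPA
  area as much as texture granularity; interpret it jointly with area.
* The rise-plateau stopping rule typically keeps 3-6 features on phantoms;
  it reproduces the qualitative "rise then plateau" behavior, not any
  specific published cardinality.
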
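# Methods

This note documents the models, conventions and numerical choices behind
`microdyn`, in the spirit of a methods section: what each stage assumes, what
the synthetic data do and do not emulate, and where genuinely open design
choices were resolved.

## Scope and data model

The pipeline begins at **binary masks**. Real two-photon data reach that
representation through projection, denoising and segmentation steps that are
inherently instrument- and operator-specific (often a trained pixel
classifier); `microdyn` provides a deterministic alternative (median +
Gaussian filtering, optional translation-only registration, Otsu or fixed
thresholding) and accepts externally produced masks unchanged, since every
analytic quantity downstream is defined on {0,1} images. Registration is
integer-pixel translation by cross-correlation so that binary masks stay
binary; sub-pixel registration would require re-thresholding and is out of
scope.

Two acquisitions per animal per session are assumed, mirroring the standard
chronic-imaging design: a wide low-zoom field for soma analysis and a
high-zoom 12-frame hour-long time-lapse (5-minute intervals) for process
dynamics. Pixel sizes are always explicit parameters; the simulator defaults
to 0.25 µm/px for the high-zoom field (a typical value at 4× digital zoom)
and 1 µm/px for the wide field, but nothing is hard-coded to these values.

## Soma extraction and spatial statistics

Somas are found by morphological opening (disk, default radius 2 µm), which
removes thin processes, followed by connected-component analysis with an
area gate (default 20–400 µm²). Centroids are component centers of mass of
pixel centers, 0-based, converted to µm; labels are assigned in raster order.

- **NND / spacing index.** Within a timepoint, each soma's nearest-neighbor
  distance is computed with a k-d tree; density is count over the ROI area
  (taken as the full field unless specified); spacing index =
  (mean NND)² × density. No edge correction is applied — edge cells have
  truncated neighborhoods, which biases the index slightly below its
  interior-limit value of 1 for a perfect grid (the 10×10-grid check allows
  5% for exactly this reason).
- **Histograms** use half-open bins [0,10), [10,20), …, [50,∞) µm and are
  reported as percentages summing to 100.
- **Loss/gain** uses greedy globally-closest one-to-one matching between the
  baseline and target soma sets, with a configurable match radius (default
  20 µm, reported in output metadata) and deterministic tie-breaking by
  label order. Unmatched baseline somas are lost, unmatched target somas
  gained, both as percent of the baseline count. The alternative net-count
  reading (sign of the count change) is available as
  `spatial.net_percent_change`.
- **Displacement** is deliberately a different quantity: for each reference
  soma, the distance to the nearest target soma, with many-to-one assignment
  allowed. Because individual cells are not tracked, this is a lower bound
  on true soma movement at the population level, and is kept separate from
  the one-to-one matcher. The "stable" fraction is the percent below 10 µm.

## Process dynamics

For each consecutive frame pair, positive pixels are classified by overlay:
stable (both frames), extension (second only), retraction (first only).
These satisfy exact identities (stable + retracted = first frame's
positives; stable + extended = second's) which the tests assert on every
pair. The **motility index** is (extended + retracted)/stable per pair,
averaged over the session's pairs (11 pairs of a 12-frame session); a pooled
variant (sum over all pairs before dividing) is exposed as an option. A pair
with zero stable pixels makes the session value missing (NaN) rather than
infinite, so downstream percent-change arithmetic never propagates
infinities. **Coverage** is the positive fraction of the first frame;
**surveillance** the positive fraction of the union over frames; the ratios
motility/coverage and motility/surveillance use the percent-scale
denominators — the within-animal baseline normalization cancels any constant
scale factor, so the scale choice does not affect longitudinal conclusions.

## Single-cell morphology

The soma is separated from the processes by opening with a configurable disk
(default 2 µm), taking the component containing the (optional) manual seed,
or the largest component otherwise. Process fragments confined to a 1-pixel
halo of the soma are absorbed into it: these are rasterization residue of
the opening, not branches (a real branch extends beyond the halo). The
partition is exact by construction: soma + process = cell, disjoint.

Shape descriptors follow ImageJ conventions: circularity 4πA/P² clamped at
1.0, with the perimeter estimated by weighted 4-neighborhood boundary
counting (for a digital disk of radius 50 px this yields circularity ≈ 0.92,
the same systematic behavior ImageJ shows); aspect ratio and roundness from
the moments-based best-fit ellipse; solidity from the convex hull.
Single-pixel or collinear masks have undefined axes and are flagged missing.

**Sholl analysis** samples each circle at sub-pixel arc steps (≤ 0.5 px); a
sample is positive when the pixel containing the point is positive, and
consecutive positive samples (circularly) merge into one crossing, so a
circle lying entirely inside a filled region counts once. Radii default to a
2 µm step. Because which radii enter the "mean intersections" summary is a
convention, both variants are emitted: the mean over the curve's support (up
to the last positive crossing; the default summary) and the mean over all
sampled radii. AUC is trapezoidal over the sampled range.

## Longitudinal assembly

All metrics flow into a tidy long table (animal, group, session, metric,
value) with percent change `100·(value/baseline − 1)` computed within animal
and metric; the baseline maps exactly to 0, and a missing or zero baseline
flags the series missing with a recorded reason. Group summaries are mean ±
SEM over animals (cell-level values are averaged within animal first — the
animal is the unit of replication). PCA standardizes columns by default
(parameters have incommensurate units) after dropping constant or
all-missing columns with a warning; correlation matrices are
pairwise-complete Pearson with two-sided p-values and a 0.05 significance
flag, uncorrected for multiplicity (they are descriptive); regression is
ordinary least squares with the standard t-test on the slope. Inferential
modeling of group × time effects (mixed-effects models, ANOVA and post-hoc
corrections) is deliberately out of scope: the pipeline's product is the
tidy per-animal table that any statistics package consumes.

## The synthetic cohort

The simulator's job is a known, recoverable ground truth with the right
statistical structure, not biophysical realism.

- **Placement**: hard-core rejection sampling (pairwise soma distance ≥
  `min_soma_separation_um`, default 20 µm) emulates territorial spacing;
  an explicit capacity error reports the achievable count when a requested
  density cannot pack.
- **Cells**: a filled soma disk (default radius 3.5 µm) with
  `n_branches_per_cell` (default 6) one-pixel-wide paths of length
  `branch_length_um` (default 25 µm) grown from the soma rim; headings are
  equally spaced, and with `branch_tortuosity > 0` they random-walk along
  the path. Straight-ray cells (`tortuosity = 0`) have exactly known Sholl
  geometry and are used as morphology fixtures.
- **Turnover**: the rendered branch pixels form a fixed scaffold; a
  constant-size active subset (default 60% of the scaffold) is on per frame.
  Per step, each active pixel drops with probability p and the same number
  of pixels is redrawn uniformly from scaffold pixels not active in the
  previous frame — so the positive area is exactly constant and extensions
  never coincide with same-step retractions. For this rule the expected
  per-pair motility is `2pA/(S + (1−p)A)` (S soma pixels, A active process
  pixels), recorded per session as the recovery target. The replacement rule
  requires `p·f ≤ 1−f` for active fraction f; the simulator validates this.
  The recorded surveillance target uses an independence approximation across
  scaffold pixels and is therefore approximate, unlike the motility and
  coverage targets which are exact expectations.
- **Sessions**: surviving somas drift from their baseline anchor by an
  independent isotropic Gaussian per session (scale `soma_drift_sigma_um`,
  default 3 µm — chosen so baseline-referenced displacements populate the
  <10 and 10–20 µm bins, with the tail reaching higher bins at σ = 10 µm),
  so the baseline-referenced displacement is N(0, σ²I) regardless of the
  session gap. Cumulative loss/gain schedules remove or add scheduled
  fractions of the baseline count; gained cells are placed in territory
  unoccupied at baseline so they cannot masquerade as returned lost cells.
  Group effects on dynamics are programmed as per-session multipliers on the
  number of cells rendered in the time-lapse field (coverage) and on the
  turnover probability (motility).
- **What is not emulated**: grayscale texture and segmentation error (an
  optional grayscale mode adds PSF blur + Poisson noise to exercise the
  thresholding path, but the validation suite runs on clean masks), z-axis
  structure, vascular landmarks, cell-body morphology changes, and any
  mechanistic model of the insult. Passing recovery tests therefore
  demonstrates the correctness of the measurement code on data with the
  study's statistical structure — not robustness to segmentation noise on
  real images.

## Problem sizes and determinism

The default validation study is 6 + 6 animals × 7 sessions with 448² px
population fields (30 cells) and 256² px time-lapses (10 cells) — large
enough that recovered group effects sit well inside their tolerance bands,
small enough to run in seconds. Motility recovery uses 512² px fields at
turnover probabilities 0–0.4 with 5 seeds each; displacement recovery uses
400 somas so the Monte-Carlo error of the mean (≈2.6%) is well below the 10%
band. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configurations produce byte-identical
images, and per-animal/per-cell streams are spawned hierarchically so group
membership does not perturb unrelated draws.

## Known limitations

- The greedy matcher is order-dependent only at exact distance ties (broken
  by label); it is not an optimal assignment, which could differ when many
  cells drift by more than half the inter-soma spacing.
- Displacement is a lower bound by design; at drift scales approaching the
  soma separation it increasingly underestimates true movement.
- The perimeter estimator (and hence circularity) carries the usual
  digital-boundary bias (~0.92 for a large disk instead of 1); comparisons
  are meaningful within the pipeline but not against tools using a different
  estimator.
- Sholl crossing counts on 1-px-wide diagonal branches depend on the
  sampling convention near junctions by ±1; the annulus-component oracle in
  the tests bounds this discrepancy.
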
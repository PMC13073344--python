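# Methods

`mfgmorph` implements an image-based morphometric analysis (IBMA) workflow
for milk fat globules (MFGs): bright-field micrographs are segmented into
particles, each particle is measured with a fixed descriptor set, particles
are quality-filtered and classified as individual globules or agglomerates,
per-class number- and volume-weighted size metrics are derived, and two
measurement methods (typically IBMA vs laser diffraction) are compared with
a multi-step agreement analysis. This note records the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Segmentation model

Particles are dark objects on a calibrated light background. The detector
is a global threshold parameterized the way optical particle-imaging SOPs
express it:

* `calibration_intensity` (default **0.80**) — the fraction of the full
  8-bit scale taken as the calibrated background level;
* `intensity_tolerance` (default **0.20**) — the fractional darkening below
  that reference that marks foreground.

A pixel is foreground iff `I < 0.80 · 255 · (1 − 0.20) = 163.2`. Connected
components are taken under 8-connectivity by default, because a diagonal
pixel bridge between touching globules should produce one object — a
prerequisite for treating fused silhouettes as agglomerates rather than as
under-segmentation (for the same reason no watershed splitting is applied).
Components under `min_pixels` (default **25**) are dropped; components
touching the frame are excluded by default since truncated silhouettes bias
every shape descriptor; more than `max_particles` (default **200,000**)
components aborts the run. The working size range (default **1.5–130 µm**
circle-equivalent diameter) is *not* enforced during labeling but during QC
filtering, so each gated particle is individually auditable.

## Perimeter estimation

HS circularity `4πA/P²` is exquisitely sensitive to the perimeter
estimator: counting exposed pixel edges overestimates a disk's perimeter by
~27% (circularity ≈ 0.62), which would misclassify perfectly round
globules against the 0.920 class boundary. The implemented estimator is:

1. Moore-neighbor boundary tracing (Jacob's stopping criterion) → Freeman
   chain code of the outer contour through pixel centers;
2. Vossepoel–Smeulders corner-corrected weights
   `P₀ = 0.980·N_even + 1.406·N_diag − 0.091·N_corner`;
3. a half-pixel outer-offset term `+π` converting the pixel-center contour
   to the silhouette outline (offsetting a convex contour outward by r adds
   exactly 2πr).

Measured behavior: digital disks d = 12–200 px are within 1% of πd
(circularity 0.998–1.005 before clipping at 1); axis-aligned squares give
circularity 0.820 against the continuum value π/4 ≈ 0.785 (a documented
+4% perimeter bias of chain-code estimators on axis-aligned edges); a
1×10 px bar measures 20.6 against its 22.0 rectangle outline; a single
isolated pixel is assigned P = π (the outline of a diameter-1 disk).

## Convex hull, solidity, convexity, length/width

The hull is computed on boundary **pixel centers** (not corners), then
dilated outward: the hull perimeter by the same 0.5 px offset as the
particle perimeter (+π), and the hull area by a **0.35 px** offset
(`A + 0.35·P + π·0.35²`). The smaller area radius reflects that hull
vertices are *extreme* boundary centers, which sit closer to the true
silhouette boundary than the average boundary pixel; 0.35 px was calibrated
once on digital disks (d = 25–100: solidity 1.000 ± 0.006) and on the exact
stadium hull of two tangent disks (solidity 2π/(4+π) ≈ 0.880, measured
0.884). Collinear boundaries (1-px bars) fall back to the stadium around
the longest segment. Convexity (hull perimeter / perimeter) and solidity
(area / hull area) are clipped into [0, 1].

Length and width are caliper extents of the boundary along and across the
principal axis obtained from second-order pixel moments, +1 px for the
half-pixel margin. This is the instrument convention: it keeps elongation
`1 − width/length` at 0 for circles *and* squares and at 1 − h/w for
axis-aligned rectangles, whereas a max-Feret "length" would be the
rectangle's diagonal and inflate elongation for compact shapes.

Intensity statistics are the mean and **population** (1/n) standard
deviation of the masked grayscale values; the 0–255 scale is asserted, not
rescaled.

## QC filtering and classification

Exclusion (strict inequalities; values exactly at a threshold are kept):
convexity < 0.750, solidity < 0.700, area < 100 px, intensity SD < 10, or
CE diameter outside [1.5, 130] µm. Excluded records carry *every* failed
criterion. An explicit particle-id exclusion list stands in for expert
visual rejection of bubbles and membrane remnants, which is out of scope.

Classification of QC-passing particles:

* **individual** — HS circularity ≥ 0.920 and CE diameter < 25 µm;
* **agglomerate** — HS circularity < 0.920 and solidity < 0.970;
* **unclassified** — everything else.

The third bucket is retained inside the "total" count: published
instrument count tables can have class sums below the total (the packaged
counts table preserves one such row verbatim), and a three-way partition
reproduces that structure without guessing which reading is intended.

## Size-distribution metrics

Imaging observes one CE diameter per particle, so number-weighted metrics
are direct: D[1,0] is the arithmetic mean, Pn10/50/90 are number
percentiles. Volume weighting uses the sphere volume of the CE diameter
(∝ d³): D[4,3] = Σd⁴/Σd³ and Pv10/50/90 are percentiles of the cumulative
d³-weighted distribution. Applying the sphere model to agglomerate CE
diameters is a 2-D projection approximation — the price of comparability
with light-scattering outputs, which are genuinely volume-weighted in 3-D.

Both percentile families use one weighted-quantile rule: sorted values at
midpoint cumulative-weight positions, linear interpolation between
neighbors, clamped to the observed extremes. Using the same rule for both
weightings makes Pv-p ≥ Pn-p a theorem (d³ reweighting is a monotone
likelihood ratio), e.g. for {1, 2} µm: Pn50 = 1.5, Pv50 = 17/9 ≈ 1.889.
No histogram binning is involved anywhere.

## Agreement statistics

For paired per-sample metrics from two methods (differences are
method A − method B throughout):

* Pearson r with both the classical t-transform p-value and a BCa CI;
* Lin's concordance correlation coefficient with **1/n** moments (Lin's
  original convention; the 1/(n−1) variant differs by O(1/n));
* paired t-test for systematic bias (reported as NaN when the differences
  are exactly constant, e.g. a table compared with itself);
* Bland–Altman mean difference with 1/(n−1) SD and d̄ ± 1.96·SD limits;
* proportional bias: OLS slope of the difference on the pairwise mean,
  flagged significant when its **BCa CI** excludes zero (the bootstrap CI,
  not the OLS t-test, is the criterion);
* BCa bootstrap CIs, default 3000 resamples: z₀ from the fraction of
  bootstrap statistics below the point estimate, acceleration from
  jackknife skewness, endpoints taken as order statistics (never
  extrapolated), paired rows resampled jointly, deterministic under a
  seed. Resamples where the statistic is undefined are dropped; a fully
  degenerate bootstrap collapses to a point interval with a warning.

p-values are reported unadjusted; no multiplicity correction is applied.

Known property: for the mean of a Normal sample at n = 30, empirical BCa
coverage of nominal 95% intervals is ≈ 93–94% (measured 91.8–93.9% across
simulation seeds at 1000 replications × 1000 resamples). This small-sample
undercoverage is inherent to BCa, not an implementation artifact; the
implementation is cross-checked against an independent BCa reference on
skewed data in the test suite.

## Synthetic scenes

The generator emulates the study's imaging conditions: 0.0625 µm sample-
plane pixels (1.25 µm camera pixels through a 20× objective), dark globules
(level 80) on a light background (level 230), lognormal diameters with
arithmetic mean ≈ 4.4 µm (the observed individual-globule mean) truncated
to the 1.5–130 µm working range, and agglomerates as chains of 2 + Poisson
(0.8) disks overlapping at center spacing (1 − overlap)·(rᵢ + rⱼ) with
overlap 0.25 by default. Chains at overlap ≤ 0.3 reliably measure
HS circularity < 0.920, so ground-truth agglomerates are classifiable as
such. Disks are rasterized by pixel-center inclusion (hard mask) so
analytic area/perimeter oracles hold; an optional Gaussian edge blur is
available but off by default. Interiors carry a radial shading ramp
(default 60 gray levels, rim-dark to center-light), giving particles an
internal intensity SD ≈ 14 so the intensity-SD quality filter is
exercisable; set `shading_delta=0` for flat particles. Placement is
rejection sampling with non-touching silhouettes (≥ 3 px bounding-circle
clearance) and a 10,000-attempt cap that raises an error naming the
crowding parameters rather than overlapping silently.

What the generator does **not** emulate: optics (point-spread function,
vignetting, defocus), dark-field contrast, casein micelles, debris,
bubbles, membrane fragments, or 3-D structure. Passing the synthetic
end-to-end tests therefore demonstrates correctness of segmentation,
measurement, classification and bookkeeping on geometrically ideal scenes —
not robustness to the full optical complexity of real milk smears.

Problem sizes used in the validation runs: end-to-end scenes of
2000×2000 px with 100 individuals + 20 agglomerates at 0.25 µm/px (coarser
than the default pixel pitch so the scene fits a small frame while every
particle stays well above the detection floor); 10⁵ draws for the
lognormal moment-recovery check (D[1,0] within 1% of exp(µ+σ²/2), D[4,3]
within 2% of exp(µ+3.5σ²)); 1000 replications × 1000 resamples for
bootstrap coverage.

## Packaged study tables

Three CSVs transcribe the source study's per-sample tables (12 samples):
covariates, class counts/percentages, and per-class number-weighted CE
metrics with median morphology values. They are checksum-pinned and
validated at load. The reproduction report recomputes every derivable
summary (column means/SDs, storage-duration Pearson correlations) and
compares each at its printed precision. Three published rows cannot be
reconciled with the per-sample data and are reported as `flagged` rather
than pass/fail: the two storage-vs-Pn50 correlations (whose class labels
contradict recomputation) and the mean individual percentage (printed as
the complement of the agglomerate mean rather than the column mean).
Volume-weighted per-sample values and the paired method-comparison inputs
are not published, so the agreement machinery is validated on closed forms
and simulations instead of on those tables.

## Limitations

* The instrument's proprietary detection ("Sharp Edge") and its exact
  HS-circularity smoothing are not public; the documented threshold /
  chain-code scheme here is a reproducible stand-in, so absolute descriptor
  values can differ from instrument output near the class boundaries.
* Volume metrics inherit the 2-D projection approximation for
  agglomerates.
* Single-image scope: no merging of particles across adjacent fields of a
  multi-field scan.
* The classification thresholds are the study's fixed constants, not
  fitted quantities; no learning-based classification is attempted.
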
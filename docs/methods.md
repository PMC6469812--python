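# Methods

## Scope and data model

The package measures 2D cortical-bone cross-sections: a calibrated
grayscale image (`CalibratedImage`: pixel grid, isotropic pixel size in
mm, optional linear intensity calibration) is segmented into a
`SectionMasks` object (tissue, whole-section and cortical-compartment
masks, periosteal and endosteal contours, labelled pore map), from which a
fixed parameter vector is computed. The endosteal boundary is always a
supplied input — in practice a manually drawn contour — because reliable
automatic endosteal detection is a separate, unsolved problem in 2D;
the periosteal contour is traced automatically.

Conventions used throughout: images are indexed `[row, col]` with pixel
centers on the integer lattice; contours are `(x, y) = (col, row)` polygon
vertex arrays; foreground (tissue objects, pores) is 8-connected and
background 4-connected; areas are pixel counts × pixel_size².

## Segmentation

Fixed stage order (enforced and logged in the provenance record):
optional Gaussian smoothing → tissue thresholding → mask cleaning →
periosteal tracing → cortical compartmenting.

* **Thresholding.** Three methods. `otsu` maximizes between-class
  variance; `isodata` (Ridler–Calvard) iterates to the midpoint of the two
  class means; `adaptive` compares each pixel to the local mean over a
  square window (default 201 px at 12 µm/pixel) minus a configurable
  offset, and is the right tool when illumination varies smoothly across
  the field. The package default is `isodata`: with strongly unequal class
  populations (background pixels outnumber tissue roughly 3:1 in a framed
  cross-section) Otsu's optimum sits several noise standard deviations
  closer to the background level, which makes rare pore-rim
  misclassifications one-sided; the IsoData threshold is symmetric in the
  class means, so at 10% intensity noise both misclassification directions
  are ≈5σ events. A constant image has no defined global threshold; the
  result is an all-background mask with a `constant_image` provenance flag.
* **Cleaning.** 8-connected foreground objects with area strictly below
  0.144 mm² are removed (1000 px at 12 µm/pixel), then 4-connected
  background components of exactly one pixel are filled. The operation is
  idempotent.
* **Periosteal tracing.** The cleaned mask is morphologically closed with
  a disk of radius 0.48 mm (implemented exactly via two Euclidean distance
  transforms, which is orders of magnitude faster than a structuring-
  element sweep at radius 40 px); the largest component is kept, its
  interior filled, and its outer iso-contour taken as the periosteal
  polygon. The closing radius is what bridges periosteal notches narrower
  than ~2×0.48 mm.
* **Compartmenting.** The cortical mask is the filled periosteal region
  minus the interior of the endosteal polygon (single shared scanline
  polygon-fill rule for the whole package). Candidate pores are
  8-connected non-tissue components inside the compartment; components
  8-adjacent to the marrow cavity or the outside background are discarded,
  since a void touching the endosteal boundary is indistinguishable from a
  marrow notch in a single section.
* **ROI restriction.** An angular sector about the section centroid
  (default width 60°, center supplied by the user as the anteromedial
  direction); pores are kept if and only if their centroid falls in the
  sector, so a pore is never split by the sector edge.

## Morphometry

* **Po.Dm** (largest inscribed circle): per pore,
  `2·(max EDT − 0.5)·pixel_size`, where EDT is the exact Euclidean
  distance to the nearest non-pore pixel center. The −0.5 px convention
  makes a single-pixel pore one pixel wide and is unbiased (error < 1 px,
  typically −0.5…+0.2 px) for digital disks whose centers lie on the
  pixel lattice. Verified exactly against an exhaustive inscribed-circle
  search in the tests.
* **Ct.Th**: for every periosteal boundary pixel, the minimum Euclidean
  distance to the rasterized endosteal contour; Ct.Th is the midpoint of
  the most populated histogram bin (default width 1 px), ties broken
  toward the smaller distance (conservative). The mode was chosen over
  the mean to be insensitive to locally thickened or notched regions, but
  it is genuinely unstable when the wall-thickness distribution is
  bimodal with near-tied peaks — see Limitations.
* **Areas**: Tt.Ar is the filled periosteal region; Ct.Ar the cortical
  compartment *including* pores; T.Ar the mineralized tissue; Ct.Wba the
  cortical-tissue percentage of Tt.Ar. Treating Ct.Ar as compartment area
  keeps `Ct.Po = 100·pore/cortical` and Ct.Wba mutually consistent. Pore
  density Po.D uses the compartment area as denominator.
* **Stratified metrics**: thresholds {60, 100, 160, 300, 385} µm with
  strict `>` comparison. `Po.D_x` (count of pores above x per mm²),
  `relPo.n_x` (percent of pore count), `Ct.Po_x` (their porosity),
  `relCt.Po_x = 100·Ct.Po_x/Ct.Po`. With zero pores the relative metrics
  are undefined and reported missing with an explicit flag. All are
  non-increasing in x by construction; threshold 0 recovers Ct.Po and
  100%.
* **Statistics within a section** use the population SD (÷n); cohort
  summaries use the sample SD (÷(n−1)). Quantiles interpolate linearly
  between order statistics. Calibrated-intensity mean/SD over cortical
  tissue stand in for volumetric density statistics when a linear
  calibration is present.

## Synthetic sections

The generator emulates an imaged diaphyseal cross-section: a periosteal
boundary (ellipse, default semi-axes 2.0 × 1.7 mm, or a rounded-triangle
variant) and an endosteal boundary offset inward by
`offset + modulation·cos(θ − φ)` (default 0.9 ± 0.15 mm), rasterized at
12 µm/pixel as two intensity levels (tissue 26000, background 9000 on a
16-bit scale) plus Gaussian noise with SD a configurable fraction
(default 10%) of the level separation.

Pore diameters follow a two-component lognormal mixture: a "small"
Haversian component (median 40 µm, σ_log = 0.35) and a "large" remodeled
component (median 130 µm, σ_log = 0.40) with mixing weight 0.08, floored
at 30 µm (≥2.5 px, so no planted pore can be erased by the single-pixel
fill) and capped at 70% of the thinnest wall. At the default density of
17 pores/mm² this yields mean Po.Dm ≈ 52 µm (SD ≈ 35 µm), ≈8% of pores
above 100 µm carrying ≈50% of the porosity — the hallmark of a
large-pore-dominated distribution. Pores are placed as non-overlapping
circles (centers snapped to the pixel lattice so the planted diameter is
recoverable to sub-pixel accuracy; minimum 2 px clearance between pores
so 8-connectivity never merges neighbours; 3 px clearance from both
contours so no pore touches the endosteal boundary), with large pores
(>100 µm) biased toward the endosteal side by rejection sampling on the
normalized wall depth, acceptance probability `(1−t)^(4·bias)`. An
infeasible packing request fails explicitly, naming achieved vs requested
counts.

Because planted pores are circles, the generator cannot reproduce every
published combination of real-bone statistics simultaneously: real pores
are irregular, so their planimetric area exceeds the area of the largest
inscribed circle, and a real cortex with Po.D ≈ 17/mm² and mean inscribed
diameter ≈ 51 µm shows Ct.Po ≈ 11% where circular pores give ≈5–7%. The
defaults favour matching the diameter distribution and its large-pore
stratification (the quantities under study); total porosity is
correspondingly lower than in real tissue.

Ground truth: the exact contours, the planted pore list, raster-exact
areal and porosity values (recomputed from the emitted masks, which are
rasterized from the same polygons by the shared fill rule), and Ct.Th
defined by applying the thickness statistic to the true contours at the
target pixel size (the wall-profile mode is only well-defined relative to
a sampling rule; see Limitations).

## Synthetic cohorts

A cohort draws per-subject section geometry (overall scale 0.85–1.15,
wall offset 0.65–1.15 mm, pore density 13–21/mm², large-pore weight
0.02–0.16, random modulation phase) and an independent standard-normal
aBMD-like latent (rescaled to 529 ± 96 mg/cm²; the right side adds 15
units of side noise). Outcomes are planted on the *measured* morphometry,
never on ground truth:

    y_z = β₁·z(aBMD) + β₂·z(relCt.Po_100) + ε,   ε ~ N(0, σ²)

with σ² = 1 − β₁² − β₂² by default so y_z has unit variance and the
planted coefficients are recovered as standardized betas. Defaults
β₁ = 0.72, β₂ = −0.55 put the covariate-only model at adjusted R² ≈ 0.5
at n = 19. Four outcome columns are emitted per side at the physical
scales of femoral stiffness/strength under stance and fall loading
(stance 3210 ± 1343 N/mm and 2605 ± 903 N; fall 1314 ± 376 N/mm and
1456 ± 460 N); the fall cases attenuate β₂ by 0.5 and plant a −0.4 SD
left/right shift, mirroring the empirical pattern that large-pore
associations and side asymmetry concentrate differently across load
cases. Morphometry columns are produced by the morphometry module through
either of two routes: the full image chain
(rasterize → segment → measure; `morphometry_mode="image"`), or the
"analytic" fast path where the pore table is built directly from the
planted circle population and fed through the same metric formulas —
used for Monte-Carlo work at n in the hundreds, where rasterizing tens of
thousands of sections would be pointless. In the analytic path pores are
not spatially placed (positions are NaN) and Ct.Th uses the wall-offset
mode approximation.

## Statistics

Two-sided α = 0.05 throughout; no multiple-testing correction (matching
common practice in small ex vivo cohorts; flagged in the output
metadata). Missing values are handled pairwise-complete with n reported
per cell. Shapiro–Wilk gates the paired comparison: a paired t-test when
the differences pass, Wilcoxon signed-rank otherwise; identical sides
return a degenerate flag with p = 1. Pearson CIs use Fisher's z with
`z_{1−α/2}/√(n−3)`, endpoints clamped to [−1, 1]. Partial correlation is
computed by residualizing both variables on the covariate (the closed
form from the three marginal r's agrees to 1e-12 and is kept as a
cross-check), with n−3 degrees of freedom. Linear models are ordinary
least squares on z-scored variables (sample SD), so a single-predictor
standardized beta equals the Pearson r; rank-deficient designs fail
naming the collinear columns. The association-table builder reports both
raw and significance-masked coefficient columns (masked = missing where
p ≥ α), and leaves the partial block missing when the covariate is
degenerate.

## Problem sizes

Default verification sizes were chosen so every stage is exercised at
full fidelity on a desk machine: batches of 50–100 sections of ~350×350
px (~130 pores each) for recovery and oracle checks; n = 500 cohorts
(one per seed, 100 seeds) for effect-size recovery via the analytic
route; 2000/1000 Monte-Carlo replicates at n = 19 for CI coverage and
type-I error.

## Limitations

* The histogram-mode thickness statistic is unstable when the
  wall-thickness distribution has two near-tied peaks (e.g. a cosine
  offset modulation produces density peaks at both extremes): sub-pixel
  perturbations can flip the mode between peaks ~2·modulation apart.
  Under the default geometry recovery is within 1 px; for randomized
  modulation phases individual sections can report either peak.
* Circular pores understate total porosity relative to equally-sized
  irregular pores (above); no pore coalescence, no 3D structure, no
  biophysical remodeling model.
* The planted outcome model is linear with independent Gaussian noise;
  it emulates the covariance structure needed by the association stage,
  not femoral biomechanics. Passing recovery tests therefore demonstrates
  correctness of the measurement and statistics code, not validity of any
  biological claim on real data.
* The adaptive threshold is a local-mean rule: in fields much larger than
  the window that are far from any tissue it marks noise as foreground;
  it is intended for framed sections where every window straddles classes,
  or together with the cleaning stage.
* Automatic endosteal segmentation is out of scope by design; results
  inherit whatever observer variability the supplied endosteal contours
  carry.
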
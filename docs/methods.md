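# Methods

`gliovasc` quantifies neuro- and perivascular inflammation in periventricular
white matter from brightfield immunohistochemistry (IBA1 for
microglia/macrophages, GFAP for astroglia, HE as the anatomical reference),
inside regions of interest — white-matter hyperintensities (WMH) and
normal-appearing white matter (NAWM) — that were drawn on a 2D MRI slice and
transferred onto the histology grid.  This note records the models, the
parameters that matter, the design choices made where the workflow left
decisions open, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

Rasters are 0-based, row-major, origin top-left, pixel centres at integer
coordinates; points are `(x, y)` with `x` indexing columns.  Every physical
quantity derives from `pixel_size_um` (µm per pixel edge); areas in mm² are
`n_pixels x (pixel_size_um/1000)²`.  The default working resolution is
1.0 µm/pixel; the loader block-averages scans to the working resolution.
The original scan scale after export is not published, so the working
resolution is a configuration choice.

## Stain separation

Brightfield chromogens follow Beer–Lambert absorption: per channel,
`OD_c = -log10(max(I_c, 1) / I0_c)`, and `OD = M c` where the columns of `M`
are the unit-norm optical-density vectors of hematoxylin, DAB and a residual
direction (the normalised cross product of the first two).  The default `M`
is the classical published H-DAB basis; it applies to both IBA1 and GFAP
slides (both DAB-brown with hematoxylin counterstain) and is replaceable in
the configuration by nine numbers.  `I0` is estimated per image as the 99th
percentile of each channel over a 5% tissue-free margin frame, because no
background calibration is published.  Deconvolution inverts the 3×3 system
per pixel; negative concentrations (noise, basis mismatch) are clipped to
zero and the clipped share of total concentration mass is reported as a QC
metric.  The forward model used by the synthetic generator is the exact
inverse of this transform, so the unmixing is verifiable to machine
precision on noise-free floating-point renders and to ~1e-3 OD on quantised
8-bit renders.

## Registration

*MRI → HE (ROI transfer).*  Paired landmarks (operating standard ≥ 10;
fewer only warns) fit either a least-squares affine (default — formalin
distortion is mild at the 2×2 cm block scale) or an exact thin-plate-spline
interpolant (smoothing 0).  ROI masks are warped by inverse-mapping with
nearest-neighbour interpolation, so they stay strictly binary; disjointness
is re-checked and ROIs that land empty are flagged.

*Stained section → HE.*  Adjacent sections are co-registered on their
hematoxylin concentration maps by a multi-resolution (shrink 4/2/1) affine
optimisation of Mattes mutual information (SimpleITK's registration
framework; normalised correlation is a config alternative), initialised by
moments when no initial transform is given.  Convergence policy: the result
is rejected — flagging the landmark-based manual fallback — when an image
is near-constant, the similarity is non-finite, the final mutual
information is more than 0.05 nats below the initial one, or the absolute
mutual information stays below 0.1 nats.  The absolute floor exists because
a pure "gain over init" criterion would reject already-aligned pairs, where
the achievable gain is zero.  If the optimiser's last sub-pixel step scores
below the best pose seen, the better-scoring pose is returned.

## Glial quantification

*Cohort threshold.*  To absorb staining variability across subjects, the
positive/background OD cutoff is derived cohort-wide: per subject, candidate
positives are found by an Otsu cut on in-ROI DAB OD and their mean OD
recorded; the threshold is `kappa x mean(per-subject candidate means)` with
`kappa = 0.5` (the candidate mean is a centre of the positive population,
so half of it approximates the class boundary; `kappa` is config-exposed).
Per-subject means are retained so single slides can be checked against the
cohort rule.  A subject run outside a cohort falls back to a per-subject
threshold flagged "provisional".

*Segmentation.*  `(dab >= threshold) & roi`, 8-connected components, holes
filled only up to soma scale (default 40 µm² — larger enclosures between
crossing ramifications must not inflate the stained area), and a debris
filter at 20 µm² (kept when exactly at the limit).  Cells straddling the ROI
edge are clipped to the ROI.

*Morphometrics.*  Area = pixel count × pixel area.  Perimeter uses the
4-direction Crofton estimator: chain-code/contour polygon lengths read
rasterised disks ~5% long, which would bias circularity of a perfect disk
down to ~0.93–0.95; Crofton is unbiased for smooth shapes.  Circularity
`4 pi A / P²` is clamped to [0, 1] (single pixels and rasterisation can
exceed 1).  Skeleton length thins the object to one pixel and sums steps,
orthogonal as 1 and diagonal as √2, skipping diagonal steps shortcut by an
orthogonal pair; a drawn bar of length L reads within a few percent of L.

*Region outcomes.*  Frequency = objects / ROI area (mm²); area % = positive
pixels / ROI pixels; intensity % = mean positive-pixel DAB OD divided by
`od_max` (default 2.0) × 100 — the original "Intensity (%)" normalisation is
unpublished, so this definition is an explicit reconstruction and its scale
is not claimed comparable to the original reports; average length and
circularity are unweighted means over cells.  GFAP astroglia frequently fuse
into scars, so frequency/length/circularity are suppressed (NaN) for that
stain.

## Perivascular grading

Vessel lumens are detected on the HE hematoxylin map as bright (OD <
0.15), compact (solidity ≥ 0.8) regions of ≥ 80 µm² not touching the image
border, assigned to the ROI containing their centroid; a manual
lumen-outline input exists for rater-driven workflows.  The perivascular
zone is the set of pixels with Euclidean distance to the lumen in (0, 15] µm
(distance transform), intersected with tissue and excluding all lumens.
Astroglia are counted by soma centroid in the zone (a soma at exactly 15 µm
counts); density = count / zone area in mm².  Grades: scar ⇒ 3; density
> 300/mm² ⇒ 3; 100–300 inclusive ⇒ 2; any astroglia below 100 ⇒ 1; none ⇒ 0.
The boundary densities 100 and 300 both map to grade 2, reading the printed
ranges "< 100", "100–300", "> 300" literally.

Three quantities in this scheme have no published operational definition
and are pinned reconstructions, all config-exposed: the density denominator
(taken as the 15 µm annulus area), the close-range distance (5 µm from the
lumen boundary, ≤ rule), and the scar criterion (GFAP-positive pixels
covering ≥ 75% of the angles around the lumen centroid *and* ≥ 50% of the
inner-band area).  A consequence of the annulus denominator is that grades
are strongly quantised for ordinary small vessels: a single astroglia beside
a 30 µm lumen already reads ≈ 200/mm² (grade 2), so "mild" is rare and
grade-0 common in both the synthetic data and, plausibly, any literal
application of the rule; the per-ROI grade mix still moves monotonically
with the underlying density.

## Cohort statistics

Per outcome: Shapiro–Wilk normality per group and Levene homogeneity at
α = 0.05; on failure a natural log (shifted by `-min + 1e-6` when
non-positive values exist) is applied and recorded.  The adjusted model is
an ordinary linear model `value ~ group + roi + age + sex +
fixation_interval` with F tests for group and ROI — ROI is a fixed crossed
factor, not a repeated measure, mirroring the stated analysis; a mixed
model is offered behind a flag but is not the default.  With no
interactions and two-level factors, Type-II and Type-III tests coincide;
`anova_lm(typ=2)` is used.  Covariates without variation (e.g. a single-sex
cohort) are dropped with a warning.  Bonferroni families are the table
blocks: microglia (5 outcomes), astroglia (2), perivascular (5);
`p_bonf = min(1, m p)`.  Chi-square tests are Pearson without continuity
correction.  WMH-burden stratification: Fazekas 0–1 mild versus 2–3
moderate-to-severe, re-running the adjusted model with burden in place of
group.  "Multivariate ANOVA" in the emulated workflow is implemented as
separate univariate models per variable, as per-row p values imply.

## Synthetic cohort

The generator is the ground-truth instrument.  Defaults are the study
conditions: 17 hypertension vs 5 control subjects; 0.64 × 0.64 mm slides at
1 µm/px with two rectangular ROIs (NAWM, WMH) of ≈ 0.11 mm² each; microglia
at ≈ 270/mm² baseline, amoeboid fraction 0.30, per-cell DAB amount 0.75 OD,
branch length 22 µm; astroglia at 250/mm²; three vessels per ROI with lumen
radii 25–45 µm, per-vessel perivascular density targets ≈ 150/mm² baseline
and scar probability 0.03.  Each outcome follows
`baseline + group_delta·[hypertension] + roi_delta·[WMH] + covariate terms
+ burden term + N(0, sd)` and is realised through object placement; effect
*directions* follow the hypertension > control, WMH > NAWM pattern of the
emulated study, with magnitudes free parameters (`scaled_effects(k)` scales
the group contrasts; `k = 0` is the null cohort, `k = 3` the large-delta
setting).  Covariates: age ~ N(80, 8), fixation interval ~ N(11, 6) months,
Fazekas drawn group-dependently (controls 0–1, hypertension mostly 2).
Cells are disks plus poly-line arms so circularity and skeleton-length
truth are analytic; vessels are elliptical lumens with a hematoxylin wall
ring; scars are full GFAP bands around the lumen.  Perivascular placement
puts `round(density x annulus_area)` somata in the 15 µm annulus, at least
one soma radius clear of the lumen and spaced ≥ 2 soma radii + 1 px so
neighbouring somata never merge under 8-connectivity.  IBA1/GFAP sections
are rendered with a known few-pixel offset against HE (recovered by the
intensity registration), and the MRI counterpart is the HE frame sampled
through a known rotation/scale affine at 8× coarser grid, blurred and
monotonically intensity-remapped, with ≥ 10 exact landmark pairs evaluated
from the true map.  Everything is deterministic — byte-identical files —
for a fixed `CohortSpec`.

What the generator does *not* emulate: section folds/tears, stain
batch drift and uneven illumination, out-of-plane vessels, overlapping
3D tissue, scanner compression artefacts, and spatially correlated
between-cell heterogeneity.  Passing tests therefore show that the
implementation measures what it defines — on tissue-like but idealised
images — not that it would match a human rater on real slides.

Two known measurement biases on the synthetic data itself: (1) at study
densities ramified arbors touch, so segmentation merges neighbours and
undercounts microglia by roughly 5–30% per region (stronger where ramified
cells dominate); counts still track truth and group/ROI contrasts survive.
(2) The statistics draw region noise independently per (subject, ROI), so
the ordinary linear model is correctly specified for the generator; real
repeated-measures correlation would call for the mixed-model flag.

## Validation problem sizes

The automated checks run at sizes chosen to keep the full suite fast on a
single CPU: deconvolution round-trip on 10,000 random concentration
triples; 20 random affines and three synthetic MRI/histology pairs for
registration (ROI transfer Dice ≥ 0.95); 100 slides of 20–200
well-separated cells for counting (exact on noise-free renders, ≤ 2% error
at the default noise); 50 random cohorts for the amoeboid-vs-ramified
circularity sign test; 200 vessels at target densities {0, 50, 200, 350}/mm²
for grade recovery (≥ 95% agreement with generator truth); 500 null
replicates for type-I calibration and 200 per point for the power sweep;
one full 17-vs-5 cohort at the large-delta setting for direction
reproduction.  `scripts/acceptance.py` re-runs the same battery (counting
and vessel batteries at 40 slides / 120 vessels) and writes the measured
numbers as JSON.

## Known limitations

- The intensity (%) scale, close-range distance, scar criterion and density
  denominator are reconstructions; absolute values are comparable within
  this pipeline only.
- Vessel detection is automated and purely lumen-driven; collapsed vessels
  without a clear lumen are missed (the manual outline path covers them).
- The TPS option interpolates landmarks exactly and so propagates landmark
  error; with noisy landmarks the affine fit is the safer default.
- No stain normalisation across slides beyond the cohort threshold rule;
  blind stain-vector estimation is out of scope.
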
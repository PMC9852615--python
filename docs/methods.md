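# Methods

`femcort` implements a CT-based cortical mapping protocol for the
proximal femur and the statistics used to evaluate it as an
opportunistic osteoporosis screen.  Because real hip CT/DXA pairs are
not shipped with the package, every stage is exercised against synthetic
substrates with exact ground truth: a geometric CT phantom for the image
pipeline and a parametric cohort generator for the statistical pipeline.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic substrates do and do not establish.

## The measurement protocol

Bone is segmented from the HU grid by a fixed threshold, bone = HU >=
350.  (Clinical practice describes the segmentation window as
"0–350 HU"; operationally the cortical shell lies above 350 HU — the
printed cortical site means run 419–920 HU — so the mask is thresholded
at the upper edge of that window.)

Eight cross-sections are placed from landmarks:

* **S1–S3** perpendicular to the femoral neck axis at the subcephalic,
  middle and bottom sites.  The neck axis joins the subcephalic and
  neck-bottom landmark points; the middle site is their midpoint.
* **S4–S8** perpendicular to the femoral shaft axis at: 20 mm above the
  lesser-trochanter upper edge, the upper edge, the vertex, the lower
  edge, and 20 mm below the vertex.  The shaft axis is a total
  least-squares line through bone centroids of 2 mm slabs taken along
  the superior direction below the lesser trochanter, trimmed 5 mm from
  the distal end of the scan so every slab holds a complete
  cross-section.

Within each section, the in-plane anatomical direction pair (upper–lower
and anterior–posterior for the neck; medial–lateral and
anterior–posterior for the shaft) is obtained by projecting the global
anatomical axes into the plane and re-orthogonalizing.  For each
direction the *longest wall-to-wall chord* is found: the plane is
resampled at 0.1 mm on a grid aligned with the direction pair, bone
membership is the thresholded **trilinearly interpolated** HU (sub-voxel
smooth, so chord extents do not inherit voxel aliasing), and the chord
is the row of maximal outer extent.  Rasterization flattens the extent
profile into a plateau of rows tied within one raster step; the chord is
taken at the centre of the largest tied run (runs disambiguated by
distance to the contour centroid), which is the stable estimator of the
true extent argmax.  A pure "nearest the centroid" tie-break is *not*
used: on sections whose filled contour is asymmetric (the
lesser-trochanter bump shifts the centroid several millimetres medially)
it systematically drags the anterior–posterior chord off-axis.

Each chord end crossing the cortical shell yields one ROI.  The crossing
is first located coarsely on the resampled plane, then refined on a 1-D
HU profile sampled every 0.1 mm along the chord: each edge is placed
where the profile crosses the half level between the adjacent tissue
plateaus (background/cortex outside, cortex/trabecular inside), with
plateaus estimated by medians away from the edges.  Cortical thickness
(CTh) is the distance between the two refined edges.  The cortical HU is
the mean of the profile strictly inside the crossing with an inset of
min(1 mm, CTh/4) at each edge, which keeps partial-volume samples out of
the average; the protocol's description of HU extraction does not fix
this detail, and the inset is the package's choice.  Sections without an
enclosed endosteal cavity are measured to the chord midpoint and
flagged (`no-cavity`).

ROI numbering (S1→1–4, …, S8→28–31, walls in the fixed orders given in
`femcort.roi`) is pinned by the protocol's anatomical anchors: ROI 14 on
the lateral S4 cortex (vastus lateralis ridge), ROI 21 on the anterior
wall at the trochanter vertex, thick medial walls at ROIs 16 and 28.
S4 contributes no medial ROI (that wall merges with the neck), so the
total is 31.

## The CT phantom

The phantom is a union of three analytic solids in a canonical frame
(x medial, y anterior, z superior): an elliptic-cylinder shaft
(semi-axes 15 × 14 mm) with a hemiellipsoidal lesser-trochanter bump on
the medial wall (height 12 mm, axial extent ±15 mm, angular window
±60°), an elliptic-cylinder neck (semi-axes 14 × 12 mm, length 50 mm) at
a 130° neck–shaft angle, and a spherical head (radius 20 mm) with a thin
shell.  These are population-typical adult dimensions; none is fixed by
the protocol, and all are configurable.  There is no greater trochanter
and no trabecular texture — the phantom only needs the landmarks and
walls the protocol touches.

Cortical thickness and cortical HU are constant per section band along
each tube and blended angularly between the four labelled walls with a
cosine ease that is *flat at the wall directions*, so the planted value
at every chord endpoint is exact.  The inner (endosteal) surface is the
outer surface offset radially by the local thickness; because every
measured chord passes through the section centre, its crossing length
equals the radial thickness.  Wall defaults equal the printed site means
where a site mean is available (e.g. S6 anterior 3.37 mm = ROI 21;
S4 lateral 419.48 HU = ROI 14) and plausible values elsewhere (thick
medial calcar ~6 mm, lateral 3.2–4.8 mm, thin superior neck cortex
2 mm).  Tissue HU: cortical per wall (419–920), trabecular 150,
background 40 (soft tissue, not air, so the 350 HU threshold does real
work), head shell 700.

Voxelization classifies sub-voxel sample points (default 3× per axis,
applied only to voxels adjacent to a material boundary; interior voxels
are uniform) and averages them — i.e. ideal partial-volume mixing with
no scanner blur, noise or beam hardening.  Optional i.i.d. Gaussian HU
noise is seeded and off by default.  An arbitrary rotation can be
applied to the whole geometry (solids, landmarks, anatomical axes) to
exercise the pipeline off-grid.

Measured accuracy on the default noise-free phantom: mean |CTh error|
over the 31 ROIs is 0.13 mm at 1.0 mm voxels, 0.04 mm at 0.5 mm and
0.02 mm at 0.25 mm (worst ROI 0.10 mm at 0.5 mm); HU errors at 0.5 mm
are below 4 HU.  Rotating the phantom 30° about an oblique axis changes
no ROI by more than 0.14 mm / 3.8 HU at 0.5 mm voxels.  These numbers
are what the test suite asserts (at 0.2 mm / 5 HU bands); they show the
*protocol implementation* is sub-voxel accurate on clean partial-volume
data, not that it is robust to scanner blur, motion, osteophytes or
fractured anatomy.

## The synthetic cohort

The continuous block — hip and lumbar BMD plus 31 CTh and 31 HU site
values — is multivariate normal with configurable marginal means/SDs and
pairwise correlations; rows violating bare-positivity floors are
redrawn.  The floors are a safety net against unphysical draws, not an
active truncation: under the default moments they bind for well under
1% of rows, so the configured means, SDs and correlations are recovered
essentially unbiased (an active floor would visibly distort them).
Defaults: printed site moments and printed hip-BMD correlations
(0.445–0.523) where available; 3.5 ± 0.8 mm / 600 ± 150 HU and
correlation 0.3
elsewhere; an exchangeable 0.3 block among sites (site–site correlations
are not published — this is a modelling choice, not a claim about the
study); hip–lumbar BMD 0.5; lumbar–site 0.15.  Positive definiteness is
checked by Cholesky at validation.

T-scores are affine in BMD, T = (BMD − μ_ref)/σ_ref, with the
young-adult reference recovered in closed form from printed summary
moments: σ_ref = SD_BMD/SD_T and μ_ref = mean_BMD − mean_T·σ_ref
(hip: μ_ref ≈ 0.9445 g/cm², σ_ref ≈ 0.1387 g/cm²).  Osteoporosis status
is the WHO rule, min(T) < −2.5 strictly.  DXA availability follows a
deterministic quota (first round(f·n) patients, default 56/375) so
tests are exact.

Outcomes are group-conditional: complications are Bernoulli with
logistic log-odds whose intercept matches the published nonosteoporotic
rate (12/180) and whose group effect matches the osteoporotic rate
(24/195) under the CTh grouping; FIM, Parker–Palmer, TUG and 2-minute
walk are normal with the published group means/SDs under the HU
grouping, clipped to instrument ranges (FIM 18–126, Parker–Palmer 0–9).
The published AO-class counts sum to 376 over 375 patients, so class
probabilities are renormalized.  Everything is reproducible from a
single seed; equal seed and parameters give byte-identical CSV.

## Screening and statistics

* Screening rules: osteoporotic iff CTh(ROI 21) < 3.185 mm or
  HU(ROI 14) < 424.97 HU; a value exactly at the cut-off is negative
  (the published groups are "≥" vs "<").  3.185 is the full-precision
  cut-off; 3.19 is display rounding.
* ROC: empirical curve over all distinct thresholds; AUC by trapezoid
  (equal to the Mann–Whitney concordance probability, which the test
  suite verifies against an O(n²) pairwise count); 95% CI by the
  Hanley–McNeil standard error with a normal approximation, clipped to
  [0, 1].  The CI method is the common SPSS-style nonparametric default;
  DeLong is out of scope.
* Cut-off: maximal Youden J = Se + Sp − 1, ties to the smallest
  threshold, reported as the midpoint of the adjacent distinct score
  values.  The empirical argmax converges at a cube-root rate: at
  2 × 100 000 points its sampling scatter is still ≈ ±0.025 mm.
* `reconstruct_confusion` enumerates all integer 2×2 tables of a given
  total whose Se/Sp round to printed values (precision inferred from the
  printed decimals) plus one auxiliary predictive value, demanding a
  unique survivor — a verification oracle for published diagnostic
  tables.  At n = 56 it uniquely recovers (TP,FP,FN,TN) = (21,9,4,22)
  and (19,4,6,27), whose held-out predictive values round to the
  published 0.7/0.846 and 0.826/0.818; without the auxiliary constraint
  the reconstruction is provably ambiguous.
* ICC: ICC(2,1) — two-way random effects, absolute agreement, single
  measures — from the mean-squares decomposition, with McGraw–Wong
  F-based confidence bounds; ICC(3,1) selectable.  The published report
  does not state the form; ICC(2,1) is the conservative default for
  multiple raters rating every subject.  Verified against pingouin's
  ICC(A,1) to 1e-9 and against the closed form σ_b²/(σ_b²+σ_e²).
* Group comparisons: Welch t by default (Student and rank-sum
  selectable; "auto" applies a Shapiro pre-test and falls back to
  rank-sum), χ² for categorical data switching to Fisher's exact test
  when any expected cell of a 2×2 table is below 5, plus a
  summary-statistics-only t-test.  No multiple-testing correction is
  applied (none is applied in the source analysis); α = 0.05.
* McNemar: exact binomial when the discordant count b + c < 25, else
  continuity-corrected χ²; the variant is selectable because a published
  McNemar statistic alone cannot identify it.

## Numerical choices and degenerate inputs

In-plane resampling 0.1 mm; chord profiles 0.1 mm with trilinear
interpolation; coordinates are world millimetres, right-handed, grid
indices 0-based; section planes are infinite planes clipped to the
volume.  Landmarks come from phantom ground truth (automatic landmark
detection is not an accuracy-bearing stage of this package).  Degenerate
cases raise typed errors rather than fabricate numbers: empty masks,
planes missing the bone, crossings shorter than one sample step,
constant inputs to correlation, single-class ROC labels, zero
denominators in predictive values (flagged as undefined), and
single-class agreement tables (Fisher p pinned to 1 with a warning).

## Problem sizes

The default suite measures phantoms at 1.0 and 0.5 mm voxels
(convergence additionally at 0.25 mm with 2× antialiasing), simulates
cohorts up to 200 000 patients for correlation recovery and 2 × 100 000
scores for AUC/cut-off recovery, and replicates the 56-patient training
scale 500× for the small-sample AUC check.  The acceptance script uses
the same sizes.

## Known limitations

The phantom is piecewise-constant partial-volume imagery; no scanner
PSF, noise texture, metal, contrast or pathology.  The cohort is
Gaussian with exchangeable site correlations; it reproduces published
first and second moments and selected pairwise correlations, not the
unknown joint distribution of real patients.  Automatic landmark
detection, DXA physics, fracture biomechanics and registration between
scans are out of scope.
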
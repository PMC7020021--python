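# Methods

This note documents the models, numerical choices and limitations behind
`cheekmorph`.  All lengths are mm, volumes mm³, areas mm², angles degrees.

## Anatomical frame and reference planes

The coordinate frame is built from bone landmarks only.  The Frankfort
horizontal plane (FH) is fitted exactly through the two porions and the
midpoint of the two infraorbital points (three constraints, no least
squares); its normal, oriented so the nasion is superior to the basion, is
the vertical axis z.  The midsagittal plane contains sella (S) and nasion
(N) and is constrained perpendicular to FH, so the anterior axis y is the
in-FH component of S→N; x = y × z points toward the patient's right and the
origin is S.  This matches radiological convention and makes "sagittal
movement" a displacement along +y.

Sided planes are parasagittal (lateral/medial cheek planes through
exocanthion/alare, mid-pupillary plane through the cornea) or coronal
(cornea perpendicular plane); the inferior cheek plane is FH-parallel
through the subnasale.  The occlusal plane passes through the
upper-incisor midpoint (U1, stored as a single midpoint landmark) and both
first-molar cusps; because the landmark table's cusp wording is ambiguous
(mesial vs buccal cusps), the plane simply uses the two U6 landmarks, which
for symmetric dentitions equals the mid-U6 construction.

The maxillary rotational angle is the FH–occlusal dihedral measured on the
occlusal plane's trace in the midsagittal plane, reported as a magnitude in
[0, 90]°.  Direction is carried by the post-minus-pre difference: positive
change = clockwise pitch (posterior impaction, occlusal plane steepening).
Note that a cephalometric occlusal-plane angle measured against a different
horizontal would give different pre/post values; only the FH-based
definition is implemented.

## Registration

The post-operative model is aligned to the pre-operative model with a
deterministic two-stage best fit: a Procrustes (Kabsch) pose from paired
non-operated landmarks (Po, Or, N, S — the exocanthion is deliberately
excluded because it borders the operated cheek region), then masked
point-to-surface ICP.  The mask keeps vertices more than 3 mm superior to
FH plus a 15 mm neighbourhood of the nasion (forehead + periorbital
anatomy); correspondences are nearest points on the fixed surface
(point-to-plane-free, exact projection), because pre/post meshes need not
share a vertex layout.  Iteration stops when the masked RMS improves by
less than 1e-4 mm or at 100 iterations (returned with `converged=False`).
Up to 2000 masked vertices are used, subsampled at even indices so runs are
deterministic.  Registration quality is certified by the RMS deviation of
masked vertices to the fixed surface; the QC gate passes iff RMS ≤ 0.5 mm
(inclusive).  QC failures exclude a patient from cohort statistics but do
not abort a run.

Because `rtree` is not a dependency, nearest-point and ray queries are
implemented in-package (`_surface.py`): a cKDTree over triangle centroids
prefilters ~12 candidate triangles per query point and the exact
point-triangle projection is evaluated on the candidates; for the meshes
this pipeline handles (triangle edge length comparable to query distances)
the candidate set is effectively exhaustive, and the test suite checks it
against a brute-force all-triangles search.

## Region volumetrics

The cheek ROI is the intersection of four half-spaces (lateral/medial cheek
planes, inferior cheek plane, FH above); boundary triangles are split at
the planes and only the anterior-facing sheet (face normal with positive
anterior component) is retained.  The average sagittal movement is

    m = ΔV / A,

with A the pre-operative patch area and ΔV the signed volume between the
pre and post surfaces over the ROI footprint.  ΔV is integrated as an
anterior height-field difference: both surfaces are sampled by parallel +y
rays on a regular x–z grid of cell size 0.4 mm (the CBCT voxel size),
keeping the outermost hit, and Σ (y_post − y_pre) · cell² is accumulated.
Height fields are robust on open clinical surfaces where boolean solid
subtraction is brittle; an independent voxel-column counting oracle (exact
per-triangle ray intersection at 0.2 mm) agrees within 2 % in the tests.
If the post surface misses more than 1 % of footprint cells the measurement
aborts rather than extrapolate.

Two properties bound the estimator's bias.  For a planar patch translated
by d, m = d exactly up to grid quantization (< 0.5 %).  For a curved patch,
ΔV integrates over the projected footprint while A is the true surface
area, so |m| ≤ |d| with relative deficit ≈ ⟨|∇h|²⟩/2 (mean squared surface
slope).  The phantom's cheek curvature is chosen in the adult-midface range
precisely so this deficit stays below ~0.7 %, i.e. under 0.05 mm for
advancements up to 5 mm.  On real faces with stronger curvature the same
systematic factor applies to bone and soft tissue alike and largely cancels
in the soft/bone ratio.

Advancement strata use half-open, left-closed bins [1,2), [2,3), [3,4),
[4,∞); published bin labels are ambiguous at shared endpoints, and a
deterministic rule is required.  Movements below 1 mm are flagged
`below-range`.  ΔV is signed (anterior positive); all-absolute reporting
would hide relapse.

## Cheek mass position

The cheek mass point is operationalized as the most anterior point of the
soft-surface profile cut by the mid-pupillary plane, restricted to the
vertical window between the subnasale and infraorbital (Or) levels; its
signed anterior distance to the cornea perpendicular plane is the cheek
mass position.  Negative values (point behind the cornea plane) are
allowed — they are exactly the deficient-cheek presentation.  The
normative reference consumed as a constant is 2.145 ± 1.201 mm from a
cohort of 60 balanced adult faces; comparisons per advancement stratum use
Welch's unequal-variance t-test from summary statistics with n = 60.
Whether the normative n should count individuals or sides is not
resolvable; 60 is used and the resulting p-values should be read
accordingly.

## Prediction model and statistics

The prediction model is zero-intercept by design: the published equations
carry no constant and zero bone movement physically implies zero passive
soft-tissue movement.  A config flag allows an intercept for sensitivity
analysis.  R² is reported as the squared Pearson correlation between
observed and fitted response — *not* the uncentred sum-of-squares ratio
that no-intercept least squares packages report by default, which would be
inflated by the nonzero mean.  This matches the relationship r ≈ √R²
between the published multiple correlations (≈0.89) and R² (≈0.788).
Partial R² per predictor is (SSE_reduced − SSE_full)/SSE_reduced with the
other predictor retained.  A predictor whose column is numerically zero
(e.g. a rotation-free cohort) keeps a zero coefficient; genuinely collinear
predictors (condition number of the scaled design > 1e8) are an error.  An
optional advancement×rotation interaction term is fitted only to report its
p-value.

Side comparisons use the paired t-test on per-patient left/right values
(sides are matched within patient); identical sides return t = 0, p = 1.
Landmark reliability uses the single-measure two-way random-effects
absolute-agreement ICC(2,1) via the standard mean-squares decomposition,
cross-checked against an independent implementation in the tests.
Normality screening is the one-sample Kolmogorov–Smirnov test against a
normal with the sample mean/SD (asymptotic p; with estimated parameters
this is conservative).  Pearson strength labels use |r| cut-offs 0.3 / 0.6
/ 0.8 with 0.8 itself labelled "strong" ("larger than 0.8" = extremely
strong).  No multiple-testing correction is applied, mirroring the source
analysis.

## Phantom generator

The phantom emulates what the analysis needs from CBCT-derived models and
deliberately nothing more: a gently curved paraboloid facial sheet
(curvature radii 400/450 mm), a per-side Gaussian cheek prominence
(σ = 10 mm; bone amplitude 0.8 mm, soft 2.0 mm), a soft surface offset
10 mm anterior of bone, and all landmarks placed consistently (FH exactly
z = 0, midsagittal exactly x = 0 in the canonical pose).  Mesh resolution
is 2 mm with the ROI-bounding coordinates snapped to grid lines, so the
surgical displacement seam falls strictly outside the ROI footprint and
the height-field integration sees a fully displaced surface.

Surgery moves bone vertices inferior to 1 mm above FH and anterior to the
coronal plane: a clockwise pitch about the lateral axis through U1 composed
with an anterior translation; dental landmarks move with the bone.  The
soft-tissue ROI receives a uniform anterior displacement a1·d + a2·θ
(defaults a1 = 0.627 mm/mm, a2 = 0.070 mm/deg) plus one smooth zero-mean
sine mode tapering to zero at the ROI boundary, scaled so its ROI average
equals the drawn record-level noise.  White per-vertex noise would average
out under ΔV/A and make R² uncontrollable; a single coherent mode does
not.  Advancement may differ between sides (blended across |x| < 8 mm at
the midline) so a 96-side experiment can carry 96 independent draws at 48
phantoms.  Finally a small random rigid scan-pose offset (2 mm / 2° by
default) is applied to the whole post-operative scan, which registration
must undo.

Cohorts are drawn with the structure the analysis assumes: per-side strata
proportions 14/34/34/14 over bins [1,2), [2,3), [3,4), [4,5.5] (uniform
within each bin — the bins plus proportions reproduce the reference mean
advancement ≈ 2.97 mm to first order), rotation Normal(3.341, 2.346²)
truncated at 0 (clockwise semantics), two sides sharing (d, θ) and
differing only in noise.  The response noise SD defaults to the analytic
calibration σ² = Var(a1·X1 + a2·X2)·(1 − R²)/R² with target R² = 0.788,
using the closed-form advancement-mixture moments and truncated-normal
rotation moments.  The baseline (pre-operative) cheek-mass position is
drawn N(−0.3, 0.5²) mm — a mildly deficient cheek, consistent with the
treated population — and the post-operative position adds the soft
response.

Fast mode evaluates the response model per record; mesh mode runs each
patient's surfaces through the full geometric pipeline.  The two agree on
soft movement within 0.1 mm at zero noise.  One caveat is inherent to the
geometry: a clockwise pitch about U1 advances the cheek-level bone ROI by
roughly 0.65 mm per degree, so in mesh-mode cohorts with rotation the
*measured* bone advancement X1 exceeds the translation parameter d and the
regression describes measured movements, not generator inputs.
Experiments that target the generating coefficients therefore either use
fast mode or set rotation to zero.

## What passing tests do and do not show

The phantom shares the real data's measurement geometry (open curved
surfaces, plane-bounded ROI, landmark-driven frame, scan-pose mismatch)
but not its biology: no anatomical variation between patients, no
swelling, no mesh topology differences between scanner exports, no
landmarking error (reliability is exercised on simulated rater noise), and
a soft-tissue response that is linear by construction.  Passing the suite
shows the estimators recover known ground truth under the stated
conditions — it does not validate the linear response model itself on
patients.

## Problem sizes and determinism

Default experiment sizes: 20 seeded cohorts of 96 sides for regression
recovery; 20 phantom pairs for the end-to-end ratio; 96 per-side
advancements (48 phantoms) for bone-movement recovery.  These sizes give
standard errors comfortably below the tolerances being checked while
keeping a full acceptance run under a minute on one CPU.  All randomness
flows from explicit seeds (numpy `SeedSequence` spawning); reports and
cohort tables are byte-identical across reruns with the same seed.
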
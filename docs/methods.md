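# Methods

## Scope and data model

`capquant` analyses segmented cross-sections of coronary vessels.  A slice is
a set of closed 2-D polygons in the imaging plane — one lumen, one outer
wall, zero or more lipid cores — plus the in-plane direction from the lumen
centroid toward the myocardium.  Slices are analysed independently (no z
coordinate, no 3-D reconstruction); co-registration of OCT and IVUS slices of
the same anatomy is assumed done upstream, and slices are paired by
(patient, timepoint, slice id).  Coordinates are millimetres.

Validation enforces: simple polygons of nonzero area, lumen inside wall, each
lipid inside the wall and not overlapping the lumen interior (boundary
contact allowed).  Validated contours are stored counterclockwise starting at
the max-x vertex — a storage convention that makes file round-trips
reproducible; it is *not* the measurement anchor (below).  Geometric
predicates use an absolute tolerance of 1e-9 mm (`GEOM_TOL`).

## The four-quarter even-spacing measurement

1. The lumen is resampled to 100 points at equal arc length along its
   polygonal boundary.  Equal arc length is the only
   parameterisation-independent reading of "evenly divided"; vertex-index
   spacing would depend on how densely each segmentation drew its points.
2. The 100 points are split into four 25-point quarters.  Q1 is the 25-point
   arc *centred* on the point whose direction from the lumen centroid is
   angularly closest to the myocardium direction; Q2–Q4 follow in the
   contour's counterclockwise order.  Centring (rather than starting) Q1 on
   the myocardium is symmetric and reproducible; each quarter owns the
   dividing point it starts with.
3. Four wall dividing points are placed at the positions on the wall
   polyline closest (Euclidean) to the four lumen dividing points; distance
   ties resolve to the lowest arc-length position.  Each wall quarter — the
   arc between consecutive wall dividing points, traversed in the lumen's
   rotational sense so indices cannot cross — is subdivided into 25
   equal-arc parts, pairing wall point i with lumen point i.
4. Wall thickness at i is ‖lumen_i − wall_i‖.  Cap thickness at i is the
   distance from lumen_i to the nearest intersection of the segment
   lumen_i→wall_i with any lipid boundary ("the lipid edge near the lumen";
   with several cores on one connector, the nearest edge wins).  Points with
   no intersection have no cap value.

**Measurement anchor.**  `quantify_slice` anchors the 100-point resampling at
the point where the ray from the lumen centroid in the myocardium direction
crosses the lumen boundary.  Because this anchor rotates rigidly with the
data, wall- and cap-thickness fields are exactly invariant under rigid
motions (verified to 1e-6 mm in the tests).  Anchoring instead at a
shape-extremal vertex (e.g. max-x) would tie sample locations to the image
axes and break that invariance at the inter-point spacing scale
(~2πr/100 ≈ 0.1 mm).

Degenerate inputs are named errors: zero-perimeter contours, point counts not
divisible by four, wall dividing points collapsing onto one location, a
myocardium ray that misses the lumen (possible only for pathologically
non-star-shaped lumens whose centroid lies outside).

## Difference statistics

Pointwise differences |CapT_OCT(xᵢ) − CapT_IVUS(xᵢ)| are taken only at
indices where **both** modalities have a cap point — an absolute difference
needs both values; unmatched cap points are counted and reported but never
enter the pooled means.  Slice, plaque and cohort means divide the summed
differences by the total matched point count (weights nⱼ), which equals the
count-weighted mean of slice means and differs from the unweighted mean of
slice means whenever nⱼ vary; both identities are asserted in the tests.
Relative errors use OCT as the gold standard: mean-level = (pooled mean
difference)/(plaque's mean OCT cap thickness); min-level =
|min_OCT − min_IVUS|/min_OCT.  Relative errors are invariant to global unit
rescaling.

**Printed-precision convention.**  The shipped per-plaque summary fixture is
a 3-decimal table.  The cohort "averages-difference" relative errors are
therefore formed from the column averages *rounded to the table's printed
precision* (0.382/0.375 mm and 0.194/0.141 mm → 1.83 % and 27.32 %); the
full-precision ratios (1.79 %, 26.94 %) are kept under `*_raw` keys.  The
fixture's per-plaque mean-level error column cannot be recomputed from the
table itself (it derives from unpublished per-point data) and is carried as
data; min-level errors recompute from the printed minima to within 0.01
percentage points.

Normality checks use the Kolmogorov–Smirnov statistic of the standardized
sample against a standard normal; paired comparisons use the two-sided
paired t test, significance at α = 0.05.  A zero-variance difference sample
is flagged degenerate (p = 1 for identical samples).  The contract is the
p-value semantics; the implementation delegates to scipy.

## Cap-index scoring and agreement

The cap index is a step function of minimum cap thickness with thresholds
200/150/65 µm, boundaries inclusive on the upper edge of the lower class
(exactly 200 µm → 2, exactly 65 µm → 4), plus index 0 for a slice or plaque
with no lipid component.  Comparisons happen in µm with a 1e-6 µm slack so
that 0.200 mm sits exactly on its boundary in binary floating point.  A
slice's index uses the slice minimum cap; a plaque's index uses the
plaque-wide minimum over all its slices' cap points.

The OCT-vs-IVUS confusion is a 4×4 count table (OCT reference rows).  Slices
scoring index 0 in either modality are excluded from it by default (the
analysis targets slices with lipid core and cap).  Per-class metrics for
class k: precision = TP/column-k total, recall = TP/row-k total,
specificity = TN/(total − row k), NPV = TN/(TN + FN).  A class absent from
the reference rows has all four metrics undefined (reported as None/NaN);
precision is additionally undefined for an empty test column.
Over/under-estimation rates count test > reference and test < reference over
a scope (all rows, or a reference subset such as the unstable classes
{2, 3}); over + under + agree = 1 on any scope.

Trend analysis takes each patient's plaque index at baseline (T1) and
follow-up (T2) per modality, classifies Δ_index > 0 / = 0 / < 0 as more
vulnerable / unchanged / more stable, and reports the fraction of patients
for which the IVUS Δ equals the OCT Δ.

## Synthetic phantoms

The generator's defaults are the study conditions: 10 patients × 2
timepoints × 17 slices (340 slices), lumen radius 1.5 ± 0.15 mm with 2 %
low-order harmonic ovality, wall thickness 1.0 ± 0.10 mm, one lipid core per
slice spanning 90 ± 15° at 0.5 mm depth.  The true cap-thickness field over
the lipid arc is parabolic, cap(u) = min + spread·u², u ∈ [−1, 1] (odd grid
so the true minimum is sampled); per-plaque baseline minima are uniform on
0.04–0.30 mm with half-normal per-slice jitter (SD 0.08 mm) and spread
0.45 mm, placing cohort mean/min cap thickness near the 0.38/0.19 mm scale
of the clinical tables and populating all index classes.  The follow-up
plaque reuses the baseline geometry with one additive cap drift per plaque
(SD 0.05 mm), so all three trend classes occur.  Everything is reproducible
from one seed.

Imaging is emulated on the radial functions about the lumen centroid — not
on raw vertices — which keeps phantoms star-convex and valid and makes the
noise scale interpretable in mm.  For resolution scale σ: a periodic
Gaussian kernel of angular width σ/r̄ smooths each radial function, and a
smooth zero-mean random Fourier field (6 harmonics) with pointwise SD
exactly σ perturbs it.  Defaults σ_OCT = 0.0175 mm and σ_IVUS = 0.175 mm are
the midpoints of the two systems' quoted 15–20 µm and 150–200 µm resolution
ranges; σ-as-resolution is a modelling choice, since no quantitative noise
model of either modality is available.  Containment is restored by
projection (wall ≥ lumen + 0.15 mm; lipid clipped ≥ 0.02 mm away from lumen
and wall), with a bounded-retry guard; σ = 0 returns the exact truth
contours.

What the phantoms do **not** emulate: speckle/texture, guidewire and
catheter artifacts, calcifications, segmentation-model failure modes,
co-registration error, or correlated (non-radial) distortions.  Passing the
recovery tests therefore shows the measurement chain is unbiased and
correctly ordered under resolution-scaled contour noise — not that clinical
OCT/IVUS errors are fully captured.

Parameter recovery degrades each truth slice per modality, quantifies it,
and reports bias and RMSE of slice mean/min cap thickness plus the
cap-index disagreement against the truth index.  The reference values are
the same measurements taken on the *noiseless* truth contours, so bias
isolates the degradation effect from the method's own 100-point sampling
(shared by both runs); the index reference uses the analytic minimum.  Two
qualitative facts the sweep reproduces: the minimum-cap estimator is
negatively biased under noise (a minimum of noisy samples), and index
disagreement is non-decreasing in σ.

## Problem sizes and numerics

The acceptance script and test suite use a 200-slice phantom cohort
(10 patients × 10 slices × 2 timepoints) for the stochastic checks — large
enough for stable Monte-Carlo ordering across the 0.02/0.08/0.18 mm sweep,
small enough to quantify in seconds (one slice ≈ 10 ms).  Contours are
256-gons (lipid arcs 65 points); at that density the polygonal
approximation of a circle is accurate to ~1e-4 mm, well inside the 1e-3 mm
tolerances used for analytic-phantom assertions.  Angles serialized to JSON
are quantized to 12 decimal degrees so write→read→write cycles are
byte-stable.

## Known limitations

* Contours must be roughly star-shaped about the lumen centroid for the
  myocardium-ray anchor; heavily folded lumens are rejected, not handled.
* Calcifications are ignored throughout (no role in the data model).
* Mean-level per-plaque relative errors in the shipped summary fixture are
  not recomputable from the fixture itself (per-point clinical data are not
  public); they are reproduced only on synthetic cohorts.
* The confusion excludes index-0 slices; cohorts where many slices lack
  lipid will see a large excluded count in the pipeline summary.
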
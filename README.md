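# capquant

Quantification of coronary plaque fibrous-cap thickness and vulnerability
from paired intravascular imaging.

Rupture-prone ("vulnerable") coronary plaques are characterised by a thin
fibrous cap over a lipid-rich necrotic core; a minimum cap thickness of 65 µm
is the accepted thin-cap fibroatheroma threshold.  Intravascular ultrasound
(IVUS) sees the whole vessel wall but at ~150–200 µm resolution it cannot
measure thin caps reliably; optical coherence tomography (OCT) resolves
15–20 µm but penetrates only 1–2 mm.  `capquant` is a library for researchers
who hold segmented contours from both modalities (lumen, outer wall, lipid
cores, per co-registered slice) and want to quantify how far IVUS cap
measurements stray from the OCT benchmark — pointwise, per plaque, and at the
level of vulnerability scoring and longitudinal trend assessment.

## What it computes

**Four-quarter even-spacing measurement.**  Each slice's lumen contour is
divided into 100 points at equal arc length and into four 25-point quarters,
quarter Q1 facing the myocardium.  Four wall dividing points are placed by
shortest distance from the lumen dividing points, each wall quarter is
subdivided into 25 equal-arc parts, and lumen/wall points are paired by
index.  Wall thickness is the paired-point distance; cap thickness is the
part of that connecting line between the lumen and the nearest lipid edge.
Points whose connector crosses a lipid core are *cap points*.

**Difference statistics.**  With OCT as the gold standard, for every matched
cap point
`Δcap(xᵢ) = |CapT_OCT(xᵢ) − CapT_IVUS(xᵢ)|`, and means pool over points —
slice `Σᵢ Δcap(xᵢ)/n`, plaque `ΣⱼΣᵢ Δcap(xᵢⱼ)/Σⱼ nⱼ`, cohort
`ΣₖΣⱼΣᵢ Δcap(xᵢⱼₖ)/ΣₖΣⱼ nⱼₖ` — never the mean of per-slice means.  Relative
error = (mean CapT difference)/(mean CapT_OCT).  Minimum cap thickness is
scanned over all cap points of a slice or plaque.

**Cap-index vulnerability scoring.**  An ordinal 0–4 index from minimum cap
thickness: 0 no lipid component, 1 > 200 µm, 2 (150, 200] µm, 3 (65, 150] µm,
4 ≤ 65 µm.  OCT/IVUS agreement is summarised by a 4×4 confusion table with
per-group disagreement, per-class precision/recall/specificity/NPV, and
over/under-estimation rates; baseline-to-follow-up index changes
(Δ_index = index(T2) − index(T1)) give per-patient vulnerability trends and a
between-modality trend agreement rate.

**Synthetic paired phantoms.**  `capquant.phantom` generates ground-truth
vessel cross-sections (harmonically perturbed circles with a lipid core under
a prescribed cap-thickness field) and images each at a chosen resolution
scale by smoothing and perturbing the contours' radial functions (defaults
17.5 µm OCT-like, 175 µm IVUS-like), so the whole pipeline is testable
without clinical data and estimator bias can be measured against truth.

The package also ships the published 20-plaque summary, 348-slice confusion
and 10-patient trend tables as plain-CSV fixtures, so every derived rate can
be recomputed with zero geometry.

## Worked example

```sh
python examples/quantify_single_slice.py
```

builds a circular lumen (r = 1.5 mm) in a circular wall (R = 2.5 mm) with a
lipid band at radius 1.7–2.2 mm spanning the 90° arc toward the myocardium,
and prints:

```
points per quarter : [25, 25, 25, 25]
wall thickness (mm): 1.0000 (expected 1.0 = R - r)
cap points         : 25 of 100 (the 90-degree lipid arc)
cap thickness (mm) : mean 0.2000, min 0.1999 (expected 0.2 = lipid inner radius - lumen radius)
```

Wall thickness recovers R − r everywhere; exactly the quarter of points whose
connectors cross the band are cap points, with cap thickness equal to the
0.2 mm gap between lumen and lipid inner edge.  The other examples cover the
paired-cohort comparison (`paired_cohort_comparison.py`), the fixtures-only
table reproduction (`reproduce_published_tables.py`), vulnerability scoring
and trends (`vulnerability_and_trend.py`) and the resolution sweep
(`resolution_sweep.py`).

A thin CLI mirrors the library: `capquant simulate | quantify | run | index |
trend | reproduce-tables` (see `capquant --help`).

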
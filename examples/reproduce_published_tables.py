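"""Recompute every statistic derived from the shipped printed tables.

The package ships the source study's per-plaque cap-thickness summary
(20 plaques), its 348-slice OCT-vs-IVUS cap-index confusion counts and its
10-patient baseline/follow-up index table as plain-CSV fixtures.  This
script recomputes all derived rates from those raw numbers.
"""

from capquant import reproduce_tables

r = reproduce_tables()

t1 = r["table1"]
print("-- per-plaque cap thickness summary (20 plaques) --")
print(f"cohort mean CapT  : OCT {t1['cohort_mean_capt_oct_mm']:.3f} mm, "
      f"IVUS {t1['cohort_mean_capt_ivus_mm']:.3f} mm "
      f"-> averages differ by {t1['avg_mean_rel_err_pct']:.2f}%")
print(f"cohort min  CapT  : OCT {t1['cohort_min_capt_oct_mm']:.3f} mm, "
      f"IVUS {t1['cohort_min_capt_ivus_mm']:.3f} mm "
      f"-> averages differ by {t1['avg_min_rel_err_pct']:.2f}%")
print(f"per-plaque errors : mean-level avg {t1['mean_plaque_mean_rel_err_pct']:.2f}%, "
      f"min-level avg {t1['mean_plaque_min_rel_err_pct']:.2f}% "
      f"(range {t1['min_plaque_min_rel_err_pct']:.2f}-{t1['max_plaque_min_rel_err_pct']:.2f}%)")

t2 = r["table2"]
print("\n-- cap-index agreement (348 slices, OCT reference) --")
print(f"group disagreement: index 1/2/3 = "
      + "/".join(f"{g:.2f}%" for g in t2["group_disagreement_pct"][:3]))
print(f"overall {t2['overall_disagreement_pct']:.2f}%, "
      f"unstable groups (index 2-3) {t2['restricted_disagreement_pct']:.2f}%")
print(f"IVUS overestimates {t2['over_pct']:.1f}% / underestimates {t2['under_pct']:.1f}% "
      f"of slices (restricted: {t2['over_restricted_pct']:.1f}% / {t2['under_restricted_pct']:.1f}%)")

print("\n-- IVUS detection of the OCT cap index --")
for k in (1, 2, 3, 4):
    m = r["table3"][f"index{k}"]
    fmt = lambda v: "None" if v is None else f"{v:.2f}%"
    print(f"index {k}: precision {fmt(m['precision'])}, recall {fmt(m['recall'])}, "
          f"specificity {fmt(m['specificity'])}, NPV {fmt(m['npv'])}")

t4 = r["table4"]
print(f"\n-- vulnerability trend, baseline -> follow-up ({t4['n_patients']} patients) --")
print(f"OCT delta indices : {t4['delta_oct']}")
print(f"IVUS delta indices: {t4['delta_ivus']}")
print(f"modalities agree on the trend for {t4['agreement_pct']:.0f}% of patients")
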
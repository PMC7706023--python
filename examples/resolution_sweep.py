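"""How imaging resolution degrades cap-thickness and vulnerability accuracy.

Degrades one ground-truth cohort at three contour-noise scales spanning the
OCT-to-IVUS resolution range, quantifies each copy and reports the bias of
the recovered cap thickness and the cap-index disagreement against truth.
"""

from capquant import PhantomSpec, generate_truth, recover_parameters

truth = generate_truth(PhantomSpec(n_patients=6, slices_per_plaque=5, seed=4))
sigmas = {"s020": 0.02, "s080": 0.08, "s180": 0.18}
report = recover_parameters(truth, sigmas, seed=4)

print(f"{len(truth)} slices per level\n")
print("sigma (mm)  mean-cap bias (mm)  min-cap bias (mm)  index disagreement")
for name in ("s020", "s080", "s180"):
    r = report[name]
    print(f"  {r['sigma_mm']:.3f}        {r['mean_cap_bias_mm']:+.4f}            "
          f"{r['min_cap_bias_mm']:+.4f}            {100 * r['index_disagreement']:5.1f}%")
# The minimum-cap estimator is systematically biased low under noise (the
# minimum of noisy samples), so vulnerability is increasingly overestimated
# and index agreement decays as the noise scale approaches the IVUS range.
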
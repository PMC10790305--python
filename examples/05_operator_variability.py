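"""Inter-operator reproducibility on one synthetic case.

Processes the same case twice — once with the true operator inputs and once
with inter-operator jitter (σ = 3 mm on the mitral-valve sphere, the
dominant source of shape disagreement) — and prints the full agreement
report the pipeline computes between paired models.
"""

from lamp.pipeline import CaseConfig, compare_pair, run_case

a = run_case(CaseConfig(output_dir="scratch/example_caseA", synthetic_seed=7))
b = run_case(CaseConfig(output_dir="scratch/example_caseB", synthetic_seed=7,
                        operator_mode="inter", operator_seed=2))
rep = compare_pair(a, b).to_dict()

shape = rep["shape"]["all"]
print(f"shape:   Hausdorff {shape['hausdorff']:.2f} mm, mean {shape['mean']:.3f} mm, "
      f"median {shape['median']:.3f} mm")
print(f"fibres:  {100 * rep['fibre']['fraction']:.1f}% of matched elements within 22.5°")
print(f"fibrosis scores A: { {k: round(v, 3) for k, v in rep['fibrosis_scores_a'].items()} }")
print(f"fibrosis scores B: { {k: round(v, 3) for k, v in rep['fibrosis_scores_b'].items()} }")
lat = rep["lat"]
print(f"LAT:     r = {lat['pearson_r']:.3f}, |ΔTAT| = {lat['abs_tat_diff_ms']:.2f} ms")
print(f"CV:      mean difference {rep['cv']['mean_diff']:+.4f} m/s")
print(f"PS maps: r = {rep['ps']['pearson_r']:.3f}, SSIM = {rep['ps']['ssim']:.3f}")
# Small mean distances with a large Hausdorff tail (driven by mitral-valve
# placement), high LAT correlation with a few-ms total-activation-time
# difference, and a near-zero mean CV difference are the expected signature
# of operator variability; the PS maps agree moderately (SSIM well below 1).
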
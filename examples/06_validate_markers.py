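"""Validate a planted plasma marker against the liver disease axis.

PC1 of the liver protein matrix separates diseased from control animals; a
genuine secreted biomarker's plasma intensity should predict PC1 much
better than PC2 or PC3.
"""

from fibromark.benchmarks import pc_regression_structure

res = pc_regression_structure(n_seeds=5, seed=7)
print("per-seed regression r2 of a planted marker's plasma intensity "
      "against liver-protein PCs:")
print(f"{'seed':>4} {'PC1':>7} {'PC2':>7} {'PC3':>7}  PC1 best?")
for i, (r2, best) in enumerate(zip(res["r2"], res["pc1_best_per_seed"])):
    print(f"{i:>4} {r2[0]:7.3f} {r2[1]:7.3f} {r2[2]:7.3f}  {best}")
print(f"\nPC1 dominates in {100 * res['frac_pc1_best']:.0f}% of seeds — the "
      "plasma signal tracks the disease axis, not incidental variation")
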
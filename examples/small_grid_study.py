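"""A desk-scale rerun of the simulation study (minutes, not hours).

Runs the full 8-contrast grid at two sample sizes with 50 replicates per
condition, then prints the two study-level results: the pooled correlation
matrix of the four indices, and the per-condition bias/precision/coverage
summary for the most diagnostic contrast (delta=2, sigma=5: mean difference
under a 5:1 SD ratio). Takes a couple of minutes; scale n_reps/n_boot up for
smoother numbers.
"""

import ovlsim as ov

cfg = ov.RunConfig(
    ns=(50, 300),
    n_reps=50,
    master_seed=7,
    boot=ov.BootConfig(n_boot=100),
)
table = ov.run_grid(cfg)

print("pooled Pearson correlations (magnitudes):")
print(ov.correlation_matrix(table, absolute=True).abs().round(3))

summary = ov.summarize(table)
hetero = summary[(summary["delta"] == 2.0) & (summary["sigma"] == 5.0) & (summary["alpha"] == 0.0)]
cols = ["n", "index", "theta", "rmb", "nrmse", "coverage"]
print("\ndelta=2, sigma=5, alpha=0 (heteroscedastic mean shift):")
print(hetero[cols].to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
print("\nReading: d and the kernel overlap stay nearly unbiased with honest "
      "coverage, while\nthe parametric overlap misses the true shared mass "
      "badly — its normal equal-variance\nformula no longer describes these "
      "populations — and its interval almost never covers.")
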
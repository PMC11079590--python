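"""Two-sample MR for one exposure/outcome pair, with the full battery.

Builds a small synthetic dataset with a known causal effect (beta = 0.3),
harmonizes the two traits, and runs every estimator plus the sensitivity
diagnostics.  With clean instruments the ratio-based estimators agree
near 0.3, the heterogeneity Q p-value is unremarkable and no instrument
is flagged as an outlier.
"""

import numpy as np

from protmr import TraitInfo, harmonize, run_mr_battery, simulate_gwas

rng = np.random.default_rng(7)
k = 12
eaf = rng.uniform(0.1, 0.4, k)

exposure_trait = TraitInfo("ldl", "quantitative", 400_000, sd_y=1.0)
outcome_trait = TraitInfo("cad", "binary", 500_000, n_cases=60_000)

# instruments explain the exposure strongly (z ~ 8-14)...
true_exposure = rng.uniform(0.012, 0.045, k)
exposure = simulate_gwas(true_exposure, eaf, 400_000, exposure_trait, seed=1)
# ...and act on the outcome only through the exposure, slope 0.3
outcome = simulate_gwas(
    0.3 * true_exposure, eaf, 500_000, outcome_trait, seed=2,
    variant_ids=exposure.variant_ids,
    effect_allele=exposure.df.effect_allele.tolist(),
    other_allele=exposure.df.other_allele.tolist(),
)

pairs = harmonize(exposure, outcome)
report = run_mr_battery(pairs, seed=11)

print(f"{len(pairs)} harmonized instruments, effects model: {report.effects_model}")
for name, est in report.estimates.items():
    print(f"  {name:16s} beta={est.beta:+.3f}  se={est.se:.3f}  p={est.pval:.2e}")
het = report.heterogeneity["ivw"]
print(f"heterogeneity: Q={het.Q:.2f} (df={het.df}), p={het.q_pval:.3f}, I2={het.i2:.1f}%")
print(f"Egger intercept p={report.egger_fit.intercept_p:.3f} "
      f"(directional pleiotropy flag if < 0.05)")
print(f"global pleiotropy test p={report.presso.global_pval:.3f}, "
      f"outliers: {report.presso.outlier_ids or 'none'}")
print("\nIVW, median and mode estimators cluster near the simulated causal")
print("effect of 0.30; Egger pays for its free pleiotropy intercept with a")
print("much wider interval. Unremarkable Q, intercept and global-test")
print("p-values say the instruments act through the exposure only.")
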
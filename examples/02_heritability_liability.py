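"""Estimate case-control SNP heritability on the liability scale.

Simulates an ascertained cohort with known liability h2 = 0.4, builds
the GRM, fits AI-REML on the observed 0/1 scale, and converts to the
liability scale with the ascertainment correction — the estimate should
bracket 0.4 within ~2 standard errors.
"""

import numpy as np

from gremlite import LiabilityParams, compute_grm, fit_reml
from gremlite.sim import SimConfig, simulate_case_control_cohort

cfg = SimConfig(
    n_samples=1000, n_snps=1500, maf_spec=(0.05, 0.5),
    per_partition_h2={"all": 0.4}, prevalence_K=0.1,
    target_case_fraction=0.5, seed=11,
)
geno, labels, truth = simulate_case_control_cohort(cfg)
grm = compute_grm(geno)
lp = LiabilityParams(K=cfg.prevalence_K, P=float(labels.mean()))
fit = fit_reml(labels.astype(float), None, [grm], component_names=["genome"], liability=lp)

print(fit.summary())
print(f"\nliability transform factor (K={lp.K}, P={lp.P:.2f}): {lp.factor:.4f}")
print(f"h2 on the liability scale: {fit.h2_liab[0]:.3f} +/- {fit.h2_liab_se[0]:.3f} "
      f"(simulated truth 0.4)")
# The observed-scale h2 of a 50%-case ascertained sample understates the
# liability-scale value; the closed-form probit correction rescales it.
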
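"""Covariate-adjusted GWAS with and without the skin-color covariate.

Simulates a cohort in which designated pigmentation loci drive both an
ordinal 1-10 skin color and part of the disease liability, then scans
all SNPs by logistic regression twice — with and without skin color as a
covariate — and shows how the pigmentation loci's association shifts
when the phenotype pathway they act through is conditioned away.
"""

import numpy as np

from gremlite.assoc import gwas_logistic
from gremlite.sim import SimConfig, simulate_genotypes, simulate_liability_phenotype, simulate_skin_color

cfg = SimConfig(
    n_samples=2000, n_snps=600, maf_spec=(0.2, 0.5),
    per_partition_h2={"pigment": 0.20, "other": 0.20},
    causal_fraction=1.0, prevalence_K=0.3, seed=31,
)
geno = simulate_genotypes(cfg)
pigment_idx = np.arange(3)
other_idx = np.arange(300, 303)
labels, truth = simulate_liability_phenotype(
    geno, cfg, partition={"pigment": pigment_idx, "other": other_idx}
)
pigment_ids = geno.snps["snp"].iloc[pigment_idx]
other_ids = geno.snps["snp"].iloc[other_idx]
# skin color is driven by the same pigmentation loci, scaled by their
# liability effects, with little extra noise
pigment_effects = dict(zip(pigment_ids, 3.0 * truth.effects["pigment"]))
geno.samples["skin_color"] = simulate_skin_color(
    geno, pigment_effects, noise_sd=0.4, seed=32
)

plain = gwas_logistic(geno, status=labels.astype(float))
adjusted = gwas_logistic(geno, status=labels.astype(float), include_skin_color=True)

for name, scan in (("without skin color", plain), ("with skin color   ", adjusted)):
    t = scan.table.set_index("snp")
    print(f"{name}: lambda = {scan.lambda_gc:.2f}, "
          f"median p at pigmentation loci = {t.loc[pigment_ids, 'p'].median():.2e}, "
          f"at other risk loci = {t.loc[other_ids, 'p'].median():.2e}")
# Conditioning on skin color absorbs the pigmentation pathway: the
# pigmentation loci's p-values weaken by orders of magnitude while risk
# loci acting outside that pathway keep (or sharpen) their signal.
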
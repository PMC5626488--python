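"""Partition heritability by chromosome and regress h2 on chromosome length.

Most causal variance (0.35 of 0.5) is planted on the *shortest*
chromosome of an 8-chromosome panel, the rest spread genome-wide; the
joint multi-GRM fit should attribute the concentrated signal correctly,
and the h2-vs-length regression should flag the loaded chromosome as an
outlier — the oligogenic signature (signal concentrated in few regions)
as opposed to a polygenic one (h2 proportional to chromosome length).
"""

import numpy as np

from gremlite.architecture import chromosome_lengths, h2_length_regression, per_chromosome_h2
from gremlite.sim import SimConfig, simulate_genotypes, simulate_liability_phenotype

cfg = SimConfig(
    n_samples=800, n_snps=1600, maf_spec=(0.1, 0.5),
    per_partition_h2={"load": 0.35, "bg": 0.15}, causal_fraction=0.8,
    n_chromosomes=8, seed=21,
)
geno = simulate_genotypes(cfg)
shortest = chromosome_lengths(geno).idxmin()
loaded = np.flatnonzero((geno.snps["chrom"] == shortest).to_numpy())
rest = np.flatnonzero((geno.snps["chrom"] != shortest).to_numpy())
_, truth = simulate_liability_phenotype(
    geno, cfg, partition={"load": loaded, "bg": rest}
)

part = per_chromosome_h2(geno, truth.liability, None)
print(part.table[["label", "n_snps", "h2_obs", "h2_obs_se"]].to_string(index=False))
print(f"\nsum of per-chromosome h2: {part.table['h2_obs'].sum():.3f} (truth 0.5)")

reg = h2_length_regression(part.table, chromosome_lengths(geno))
print(f"h2 ~ length regression: r = {reg.r:.2f}, p = {reg.p_value:.2f}")
print(f"signal planted on chromosome {shortest} (the shortest)")
print(f"chromosomes outside the 95% band: {reg.outliers or 'none'}")
# With the bulk of the signal on the shortest chromosome, h2 is
# anti-correlated with length and the loaded chromosome escapes the
# confidence band of the fitted line.
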
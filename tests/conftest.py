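import numpy as np
import pandas as pd
import pytest

from gremlite.io import GenotypeMatrix
from gremlite.sim import SimConfig, simulate_genotypes, simulate_liability_phenotype


def make_geno(X, chrom="1", pos=None, snp_ids=None):
    """Wrap a raw dosage matrix in a GenotypeMatrix with minimal metadata."""
    X = np.asarray(X, dtype=np.int8)
    n, m = X.shape
    samples = pd.DataFrame(
        {"fid": [f"F{i:04d}" for i in range(n)], "iid": [f"I{i:04d}" for i in range(n)]}
    )
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    snps = pd.DataFrame(
        {
            "snp": snp_ids if snp_ids is not None else [f"s{j:05d}" for j in range(m)],
            "chrom": chroms,
            "pos": pos if pos is not None else np.arange(1, m + 1),
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(samples=samples, snps=snps, X=X)


@pytest.fixture(scope="session")
def toy_cohort():
    """Small complete cohort with a known 30% polygenic liability h2."""
    cfg = SimConfig(
        n_samples=200,
        n_snps=400,
        maf_spec=(0.1, 0.5),
        per_partition_h2={"all": 0.3},
        n_chromosomes=3,
        seed=42,
    )
    geno = simulate_genotypes(cfg)
    labels, truth = simulate_liability_phenotype(geno, cfg)
    return geno, labels, truth, cfg
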
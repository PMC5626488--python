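"""Permutation test for cis-eQTL enrichment among top GWAS signals.

The observed statistic is the number of annotated (skin cis-eQTL) SNPs
among the top-k most significant SNPs of the case-control scan.  Its
null distribution is built by re-running the full covariate-adjusted
GWAS under B label permutations: case/control status is shuffled across
samples while genotypes — and therefore the LD structure — and
covariates stay fixed to their samples.  The empirical p-value is the
proportion of permuted scans whose annotated count reaches the observed
count; ties count as exceedances by default because the strict
more-than rule degenerates to p = 0 when the annotation saturates the
top list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gremlite.assoc import AssocTable, gwas_logistic
from gremlite.io import GenotypeMatrix

__all__ = ["EnrichmentResult", "empirical_p", "eqtl_enrichment"]


def empirical_p(observed: float, permuted_counts, tie_rule: str = "inclusive") -> float:
    """Proportion of permuted counts reaching (or exceeding) the observed.

    ``inclusive`` counts ties as exceedances (conservative); ``strict``
    counts only permuted values strictly above the observed one.
    """
    permuted = np.asarray(permuted_counts)
    if permuted.size == 0:
        raise ValueError("no permuted counts")
    if tie_rule == "inclusive":
        return float(np.mean(permuted >= observed))
    if tie_rule == "strict":
        return float(np.mean(permuted > observed))
    raise ValueError("tie_rule must be 'inclusive' or 'strict'")


@dataclass
class EnrichmentResult:
    """Observed and permuted annotated counts among top-k hits."""

    observed_count: int
    permuted_counts: np.ndarray
    p_value: float
    top_k: int
    tie_rule: str
    with_skin_color: bool
    effective_B: int
    n_failed: int
    seed: int

    def summary(self) -> str:
        return (
            f"observed {self.observed_count} annotated SNPs in top {self.top_k}; "
            f"permutation mean {self.permuted_counts.mean():.1f} "
            f"(B = {self.effective_B}); empirical p = {self.p_value:.4g} "
            f"[{self.tie_rule}]"
        )


def _top_k_count(result: AssocTable, flags: pd.Series, top_k: int) -> int:
    top = result.top(top_k)
    return int(flags.reindex(top["snp"]).fillna(False).sum())


def eqtl_enrichment(
    geno: GenotypeMatrix,
    status,
    covariates,
    eqtl_flags,
    top_k: int,
    B: int,
    seed: int,
    tie_rule: str = "inclusive",
    include_skin_color: bool = False,
    skin_color=None,
) -> EnrichmentResult:
    """Annotation enrichment among the top-k association signals.

    ``eqtl_flags`` is a boolean flag per tested SNP (array in panel
    order, or a Series indexed by SNP id).  Ranking is by ascending p
    with deterministic tie-breaking (smaller p, then larger |estimate|,
    then SNP id).  Permutation scans reuse the same SNP set and covariate
    design as the observed scan; a permutation whose scan fails entirely
    is dropped and the effective B reported.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(eqtl_flags, pd.Series):
        flags = eqtl_flags.astype(bool).reindex(geno.snps["snp"])
        if flags.isna().any():
            raise ValueError("eqtl_flags must cover every tested SNP")
    else:
        arr = np.asarray(eqtl_flags).astype(bool)
        if len(arr) != geno.m:
            raise ValueError("eqtl_flags must cover every tested SNP")
        flags = pd.Series(arr, index=geno.snps["snp"].to_numpy())
    if top_k > geno.m:
        raise ValueError(f"top_k = {top_k} exceeds the {geno.m} tested SNPs")

    y = np.asarray(status)
    observed_scan = gwas_logistic(
        geno,
        status=y,
        covariates=covariates,
        include_skin_color=include_skin_color,
        skin_color=skin_color,
    )
    observed = _top_k_count(observed_scan, flags, top_k)

    rng = np.random.default_rng(seed)
    permuted = []
    n_failed = 0
    for _ in range(B):
        y_perm = y[rng.permutation(len(y))]
        try:
            scan = gwas_logistic(
                geno,
                status=y_perm,
                covariates=covariates,
                include_skin_color=include_skin_color,
                skin_color=skin_color,
            )
            permuted.append(_top_k_count(scan, flags, top_k))
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
    permuted = np.asarray(permuted, dtype=int)
    if permuted.size == 0:
        raise RuntimeError("every permutation scan failed")
    p = empirical_p(observed, permuted, tie_rule)
    return EnrichmentResult(
        observed_count=observed,
        permuted_counts=permuted,
        p_value=p,
        top_k=top_k,
        tie_rule=tie_rule,
        with_skin_color=include_skin_color,
        effective_B=len(permuted),
        n_failed=n_failed,
        seed=seed,
    )
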
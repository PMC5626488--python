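"""SNP and sample quality control.

Two preset regimes mirror common GWAS practice: a *standard* regime
(MAF < 0.02, SNP missingness > 2%, HWE p <= 1e-4, sample call rate
<= 95%) and a *stringent* regime used before heritability estimation
(MAF < 0.01, missingness > 5%, HWE p < 0.05, differential
case/control missingness p < 0.05, call rate <= 99%, pairwise
relatedness > 0.05).  Stringent filtering matters for GREML because
artifactual case-control allele-frequency differences inflate
heritability estimates.

SNP filters apply in a fixed order — autosome-only, missingness, MAF,
HWE, differential missingness — each against the then-surviving set, and
the report logs removals per step.  Comparisons are strict as printed
("MAF < 0.01" removes; MAF = 0.01 survives); the standard regime's HWE
cut is inclusive ("P <= 1e-4").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from gremlite.io import AUTOSOMES, GenotypeMatrix, GRMatrix

__all__ = [
    "QCConfig",
    "QCReport",
    "STANDARD_QC",
    "STRINGENT_QC",
    "hwe_test",
    "differential_missingness_test",
    "filter_snps",
    "filter_samples",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for one QC regime; ``None`` disables a filter."""

    maf_min: float | None = None
    snp_missing_max: float | None = None
    hwe_p_min: float | None = None
    hwe_inclusive: bool = False  # True: remove p <= threshold (standard regime)
    hwe_controls_only: bool = False
    differential_missingness_p_min: float | None = None
    sample_call_rate_min: float | None = None
    relatedness_max: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "maf_min",
            "snp_missing_max",
            "hwe_p_min",
            "differential_missingness_p_min",
            "sample_call_rate_min",
        ):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")


STANDARD_QC = QCConfig(
    maf_min=0.02,
    snp_missing_max=0.02,
    hwe_p_min=1e-4,
    hwe_inclusive=True,
    sample_call_rate_min=0.95,
)

STRINGENT_QC = QCConfig(
    maf_min=0.01,
    snp_missing_max=0.05,
    hwe_p_min=0.05,
    differential_missingness_p_min=0.05,
    sample_call_rate_min=0.99,
    relatedness_max=0.05,
)


@dataclass
class QCReport:
    """Ordered log of filters applied and what each removed."""

    axis: str  # "snp" or "sample"
    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    removed_ids: dict[str, list] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(c for _, c in self.steps)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed

    def log(self, name: str, removed: list) -> None:
        self.steps.append((name, len(removed)))
        self.removed_ids[name] = list(removed)

    def as_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n_input": self.n_input,
            "n_surviving": self.n_surviving,
            "steps": [{"filter": f, "removed": c} for f, c in self.steps],
        }


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "auto") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``method='auto'`` uses the exact conditional test when any expected
    genotype class count is below 5 and the 1-df chi-square on genotype
    counts otherwise; 'exact' and 'chisq' force a variant.  The exact
    test enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of tables no more likely
    than the observed one.  Monomorphic sites and all-zero counts return
    p = 1 (the latter with a warning).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        warnings.warn("HWE test on all-zero counts is undefined; returning p=1")
        return 1.0
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    p = nA / (2 * n)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    if method == "auto":
        method = "exact" if expected.min() < 5 else "chisq"
    if method == "chisq":
        observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
        stat = ((observed - expected) ** 2 / expected).sum()
        return float(stats.chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")
    # exact test: enumerate heterozygote counts with the parity of nA
    rare = min(nA, na)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hets) // 2
    n_cc = n - hets - n_rr  # common homozygotes
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_rr + 1)
        - gammaln(hets + 1)
        - gammaln(n_cc + 1)
        + gammaln(nA + 1)
        + gammaln(na + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs_het = n_Aa
    p_obs = prob[hets == obs_het][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def differential_missingness_test(
    missing_in_cases: int,
    called_in_cases: int,
    missing_in_controls: int,
    called_in_controls: int,
) -> float:
    """Two-sided p for the 2x2 missingness-by-status table.

    Fisher's exact test when any expected cell count is at or below 5,
    otherwise the 1-df chi-square; a zero margin (no missing calls
    anywhere, or an empty group) yields p = 1.
    """
    table = np.array(
        [[missing_in_cases, called_in_cases], [missing_in_controls, called_in_controls]],
        dtype=float,
    )
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() <= 5:
        return float(stats.fisher_exact(table.astype(int))[1])
    stat = ((table - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def _geno_counts(col: np.ndarray) -> tuple[int, int, int]:
    return int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())


def filter_snps(
    geno: GenotypeMatrix, config: QCConfig, status: np.ndarray | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply SNP filters in fixed order; returns survivors and a report.

    ``status`` (0/1 per sample) is required iff the differential
    missingness filter is enabled and restricts the HWE test when
    ``hwe_controls_only`` is set.
    """
    if config.differential_missingness_p_min is not None and status is None:
        raise ValueError("differential-missingness filter enabled but no status given")
    if config.hwe_controls_only and status is None:
        raise ValueError("controls-only HWE requested but no status given")
    report = QCReport(axis="snp", n_input=geno.m)
    keep = np.ones(geno.m, dtype=bool)
    snp_ids = geno.snps["snp"].to_numpy()

    bad = ~geno.snps["chrom"].astype(str).isin(AUTOSOMES).to_numpy() & keep
    report.log("non_autosomal", snp_ids[bad].tolist())
    keep &= ~bad

    if config.snp_missing_max is not None:
        bad = (geno.snp_missing_rate() > config.snp_missing_max) & keep
        report.log("missingness", snp_ids[bad].tolist())
        keep &= ~bad
    if config.maf_min is not None:
        bad = (geno.maf() < config.maf_min) & keep
        report.log("maf", snp_ids[bad].tolist())
        keep &= ~bad
    if config.hwe_p_min is not None:
        rows = (
            np.flatnonzero(np.asarray(status) == 0)
            if config.hwe_controls_only
            else np.arange(geno.n)
        )
        bad = np.zeros(geno.m, dtype=bool)
        for j in np.flatnonzero(keep):
            col = geno.X[rows, j]
            col = col[col >= 0]
            p = hwe_test(*_geno_counts(col))
            bad[j] = p <= config.hwe_p_min if config.hwe_inclusive else p < config.hwe_p_min
        report.log("hwe", snp_ids[bad].tolist())
        keep &= ~bad
    if config.differential_missingness_p_min is not None:
        status = np.asarray(status)
        case_rows = status == 1
        ctrl_rows = status == 0
        bad = np.zeros(geno.m, dtype=bool)
        for j in np.flatnonzero(keep):
            miss = geno.X[:, j] < 0
            p = differential_missingness_test(
                int(miss[case_rows].sum()),
                int((~miss[case_rows]).sum()),
                int(miss[ctrl_rows].sum()),
                int((~miss[ctrl_rows]).sum()),
            )
            bad[j] = p < config.differential_missingness_p_min
        report.log("differential_missingness", snp_ids[bad].tolist())
        keep &= ~bad

    return geno.subset(snp_idx=keep), report


def filter_samples(
    geno: GenotypeMatrix, config: QCConfig, grm: GRMatrix | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-rate filter, then greedy relatedness pruning.

    Relatedness pruning repeatedly finds the worst pair above
    ``relatedness_max`` and drops its member with the lower call rate
    (ties: the later sample in input order), so one removal can resolve
    a chain of related pairs.
    """
    if config.relatedness_max is not None and grm is None:
        raise ValueError("relatedness filter enabled but no GRM given")
    report = QCReport(axis="sample", n_input=geno.n)
    ids = geno.sample_ids.to_numpy()
    keep = np.ones(geno.n, dtype=bool)
    call = geno.sample_call_rate()

    if config.sample_call_rate_min is not None:
        bad = call <= config.sample_call_rate_min
        report.log("call_rate", ids[bad].tolist())
        keep &= ~bad

    if config.relatedness_max is not None:
        pos = {sid: i for i, sid in enumerate(ids)}
        unknown = [sid for sid in grm.ids if sid not in pos]
        if unknown:
            raise ValueError(f"GRM ids not among samples: {unknown[:5]}")
        gidx = np.array([pos[sid] for sid in grm.ids])
        A = grm.A.copy()
        np.fill_diagonal(A, -np.inf)
        alive = keep[gidx].copy()
        dropped: list[str] = []
        while True:
            sub = np.where(np.outer(alive, alive), A, -np.inf)
            worst = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[worst] <= config.relatedness_max:
                break
            j, k = worst
            cj, ck = call[gidx[j]], call[gidx[k]]
            if cj < ck:
                victim = j
            elif ck < cj:
                victim = k
            else:
                victim = max(j, k)  # tie: later sample order
            alive[victim] = False
            dropped.append(ids[gidx[victim]])
        report.log("relatedness", dropped)
        keep[gidx[~alive]] = False

    return geno.subset(sample_idx=keep), report
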
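"""Synthetic case-control cohorts with known genetic architecture.

The generator is the forward model the downstream analysis inverts: a
liability-threshold disease model on standardized genotypes.  Each sample
carries a latent liability

    l = sum_i  z_i * b_i  +  e,      e ~ N(0, 1 - h2_total)

where z_i are standardized dosages of the causal SNPs, effects b_i are
drawn i.i.d. normal per partition and rescaled so the realized genetic
variance of each partition's score equals its target liability-scale h2
exactly, and a sample is a case iff its liability exceeds the probit
threshold of the population prevalence K.  Case-control ascertainment
then over-samples cases to a target sample case fraction P (the study
regime is K = 2%, P = 66%), creating the bias the liability correction in
:mod:`gremlite.reml` must undo.

Genotypes are biallelic with a configurable MAF spectrum.  Optional LD is
simulated by a Gaussian copula within blocks of consecutive SNPs
(exchangeable latent correlation per haplotype draw), then thresholded to
allele counts — crude relative to real human LD, but sufficient to
exercise the GRM calibration machinery.  An ordinal skin-color covariate
(1 = very fair .. 10 = dark brown) can be driven by designated
pigmentation loci, and genic / cis-eQTL annotation labels are drawn to
match target fractions exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from gremlite.io import GenotypeMatrix, write_plink

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_liability_phenotype",
    "ascertain_case_control",
    "simulate_skin_color",
    "assign_annotations",
    "simulate_case_control_cohort",
    "write_cohort",
]


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.

    ``maf_spec`` is either a (low, high) uniform range over (0, 0.5] or an
    explicit per-SNP frequency array.  ``per_partition_h2`` maps partition
    labels to liability-scale variance fractions; with a single entry
    ``"all"`` every SNP belongs to one partition.  ``skin_color_loci``
    maps SNP ids to additive effects on the ordinal 1-10 scale.
    """

    n_samples: int = 1000
    n_snps: int = 2000
    maf_spec: tuple[float, float] | np.ndarray = (0.01, 0.5)
    ld_block_size: int = 1
    ld_r: float = 0.5
    n_chromosomes: int = 2
    per_partition_h2: dict[str, float] = field(default_factory=lambda: {"all": 0.5})
    causal_fraction: float = 0.1
    prevalence_K: float = 0.02
    target_case_fraction: float = 0.66
    skin_color_loci: dict[str, float] = field(default_factory=dict)
    skin_color_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be >= 1")
        if not 0 < self.prevalence_K < 1:
            raise ValueError(f"prevalence_K must be in (0,1), got {self.prevalence_K}")
        if not 0 < self.target_case_fraction < 1:
            raise ValueError("target_case_fraction must be in (0,1)")
        total = sum(self.per_partition_h2.values())
        if total >= 1:
            raise ValueError(f"per-partition h2 values sum to {total} >= 1")
        if any(v < 0 for v in self.per_partition_h2.values()):
            raise ValueError("negative partition h2")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not isinstance(self.maf_spec, tuple):
            maf = np.asarray(self.maf_spec, dtype=float)
            if maf.shape != (self.n_snps,):
                raise ValueError("explicit maf_spec must have one frequency per SNP")
            if not np.all(np.isfinite(maf)) or np.any(maf <= 0) or np.any(maf > 0.5):
                raise ValueError("per-SNP MAF spec must be finite and in (0, 0.5]")
        else:
            lo, hi = self.maf_spec
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi <= 0.5):
                raise ValueError(f"MAF range must satisfy 0 < low <= high <= 0.5, got {self.maf_spec}")


@dataclass
class SimTruth:
    """Ground truth recorded by the phenotype simulator for recovery tests."""

    causal_snps: dict[str, list[str]]
    effects: dict[str, np.ndarray]
    target_h2: dict[str, float]
    realized_h2: dict[str, float]
    realized_prevalence: float
    liability: np.ndarray
    genetic_score: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_snps": self.causal_snps,
            "effects": {k: v.tolist() for k, v in self.effects.items()},
            "target_h2": self.target_h2,
            "realized_h2": self.realized_h2,
            "realized_prevalence": self.realized_prevalence,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _snp_frame(n_snps: int, n_chromosomes: int) -> pd.DataFrame:
    """Contiguous blocks of SNPs per autosome, 1 kb spacing.

    Chromosome sizes taper (like real karyotypes): chromosome 1 carries
    the most SNPs and spans the most base pairs, so length-vs-h2
    regressions on simulated panels are non-degenerate.
    """
    weights = np.linspace(1.6, 0.4, n_chromosomes)
    counts = np.maximum(1, np.floor(weights / weights.sum() * n_snps).astype(int))
    counts[: max(0, n_snps - counts.sum())] += 1  # remainder to the largest
    while counts.sum() > n_snps:
        counts[counts.argmax()] -= 1
    rows = []
    i = 0
    for ci, cnt in enumerate(counts, start=1):
        for j in range(cnt):
            rows.append((f"snp{i + 1:06d}", str(ci), 1 + j * 1000))
            i += 1
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    df["a1"] = "A"
    df["a2"] = "G"
    return df


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw biallelic dosages in {0,1,2} under HWE with optional block LD.

    With ``ld_block_size == 1`` SNPs are independent.  Within a block the
    two haplotype draws of every sample share an exchangeable latent
    Gaussian correlation ``ld_r``, giving positive dosage correlation
    between SNPs of the same block.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    if isinstance(config.maf_spec, tuple):
        p = rng.uniform(config.maf_spec[0], config.maf_spec[1], size=m)
    else:
        p = np.asarray(config.maf_spec, dtype=float).copy()

    if config.ld_block_size == 1:
        X = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
    else:
        X = np.empty((n, m), dtype=np.int8)
        r = config.ld_r
        for start in range(0, m, config.ld_block_size):
            stop = min(start + config.ld_block_size, m)
            width = stop - start
            dose = np.zeros((n, width), dtype=np.int8)
            for _hap in range(2):
                shared = rng.standard_normal((n, 1))
                own = rng.standard_normal((n, width))
                z = np.sqrt(r) * shared + np.sqrt(1 - r) * own
                u = stats.norm.cdf(z)
                dose += (u < p[start:stop][None, :]).astype(np.int8)
            X[:, start:stop] = dose

    snps = _snp_frame(m, config.n_chromosomes)
    samples = pd.DataFrame(
        {
            "fid": [f"F{i + 1:06d}" for i in range(n)],
            "iid": [f"I{i + 1:06d}" for i in range(n)],
            "sex": rng.integers(1, 3, size=n),
            "age": np.round(rng.uniform(30, 75, size=n), 1),
        }
    )
    return GenotypeMatrix(samples=samples, snps=snps, X=X)


def _standardize(X: np.ndarray) -> np.ndarray:
    p = X.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    sd[sd == 0] = 1.0
    return (X - 2.0 * p) / sd


def simulate_liability_phenotype(
    geno: GenotypeMatrix,
    config: SimConfig,
    partition: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Case/control labels from the liability-threshold model.

    ``partition`` maps each label of ``config.per_partition_h2`` to the
    SNP column indices eligible to be causal for it; by default every SNP
    is eligible for every partition label.  Causal effects are drawn
    i.i.d. normal on standardized genotypes and rescaled so the empirical
    variance of each partition score equals its target h2 exactly,
    avoiding Monte-Carlo drift in recovery tests.  Returns 0/1 labels
    (case = 1) and the recorded :class:`SimTruth`.
    """
    total_h2 = sum(config.per_partition_h2.values())
    if total_h2 >= 1:
        raise ValueError(f"partition h2 values sum to {total_h2} >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n, m = geno.n, geno.m
    if np.any(geno.X < 0):
        raise ValueError("phenotype simulation requires complete genotypes")
    Z = _standardize(geno.X.astype(np.float64))

    causal: dict[str, list[str]] = {}
    effects: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    score = np.zeros(n)
    per_scores: dict[str, np.ndarray] = {}
    for label, h2 in config.per_partition_h2.items():
        pool = np.arange(m) if partition is None else np.asarray(partition[label])
        n_causal = max(1, int(round(config.causal_fraction * len(pool)))) if h2 > 0 else 0
        idx = np.sort(rng.choice(pool, size=n_causal, replace=False)) if n_causal else np.array([], int)
        b = rng.standard_normal(len(idx))
        g = Z[:, idx] @ b if len(idx) else np.zeros(n)
        v = g.var()
        if h2 > 0 and v > 0:
            scale = np.sqrt(h2 / v)
            b = b * scale
            g = g * scale
        elif h2 == 0:
            b = np.zeros(len(idx))
            g = np.zeros(n)
        causal[label] = geno.snps["snp"].iloc[idx].tolist()
        effects[label] = b
        per_scores[label] = g
        realized[label] = float(g.var())
        score = score + g

    resid_var = 1.0 - sum(realized.values())
    liab = score + rng.standard_normal(n) * np.sqrt(max(resid_var, 0.0))
    threshold = stats.norm.ppf(1.0 - config.prevalence_K)
    labels = (liab > threshold).astype(np.int8)
    truth = SimTruth(
        causal_snps=causal,
        effects=effects,
        target_h2=dict(config.per_partition_h2),
        realized_h2=realized,
        realized_prevalence=float(labels.mean()),
        liability=liab,
        genetic_score=score,
        seed=config.seed,
    )
    return labels, truth


def ascertain_case_control(
    labels: np.ndarray, target_case_fraction: float, seed: int, n_total: int | None = None
) -> np.ndarray:
    """Sample indices giving exactly round(n_total * target) cases.

    Selection is uniform at random within cases and within controls.
    Raises when either class cannot supply its quota, naming the deficit.
    """
    labels = np.asarray(labels)
    if not 0 < target_case_fraction < 1:
        raise ValueError("target_case_fraction must be in (0,1)")
    cases = np.flatnonzero(labels == 1)
    controls = np.flatnonzero(labels == 0)
    if n_total is None:
        n_total = len(labels)
    n_cases = int(round(n_total * target_case_fraction))
    n_controls = n_total - n_cases
    if len(cases) < n_cases:
        raise ValueError(
            f"insufficient cases: need {n_cases}, have {len(cases)} "
            f"(short by {n_cases - len(cases)})"
        )
    if len(controls) < n_controls:
        raise ValueError(
            f"insufficient controls: need {n_controls}, have {len(controls)} "
            f"(short by {n_controls - len(controls)})"
        )
    rng = np.random.default_rng(seed)
    pick = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    return np.sort(pick)


def simulate_skin_color(
    geno: GenotypeMatrix,
    skin_color_loci: dict[str, float],
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Ordinal skin color 1-10 driven by pigmentation-locus dosages.

    score = 5.5 + sum_l effect_l * (dosage_l - 1) + noise, rounded and
    clipped to [1, 10].  Monotone in the weighted locus score before
    noise; with zero effects and zero noise every sample gets the
    mid-scale value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    base = np.full(geno.n, 5.5)
    for snp_id, eff in skin_color_loci.items():
        j = geno.snp_index(snp_id)  # raises KeyError for unknown loci
        dose = geno.X[:, j].astype(float)
        dose[dose < 0] = np.nan
        base = base + eff * (np.nan_to_num(dose, nan=1.0) - 1.0)
    noisy = base + rng.standard_normal(geno.n) * noise_sd
    return np.clip(np.rint(noisy), 1, 10).astype(np.int8)


def assign_annotations(
    snp_ids,
    genic_fraction: float,
    eqtl_fraction_by_threshold: dict[float, float],
    seed: int,
) -> pd.DataFrame:
    """Draw genic flags and cis-eQTL p-values matching target fractions.

    ``eqtl_fraction_by_threshold`` maps p-value thresholds (e.g. 0.01,
    0.001, 0.0001) to the fraction of SNPs flagged at that threshold; a
    tighter threshold must flag a (weak) subset, so fractions must be
    non-increasing as thresholds tighten (the study regime is roughly
    23% / 10% / 6% at 0.01 / 0.001 / 0.0001).  The returned frame has one
    row per SNP with a boolean ``genic`` column and a synthetic ``eqtl_p``
    whose sub-threshold sets are nested by construction, each of size
    round(fraction * m).
    """
    snp_ids = list(snp_ids)
    m = len(snp_ids)
    if not 0 <= genic_fraction <= 1:
        raise ValueError("genic_fraction must be in [0,1]")
    thresholds = sorted(eqtl_fraction_by_threshold, reverse=True)  # loosest first
    fracs = [eqtl_fraction_by_threshold[t] for t in thresholds]
    if any(not 0 <= f <= 1 for f in fracs):
        raise ValueError("eQTL fractions must be in [0,1]")
    if any(f_next > f for f, f_next in zip(fracs, fracs[1:])):
        raise ValueError(
            "eQTL fractions must be non-increasing as thresholds tighten "
            f"(got {dict(zip(thresholds, fracs))})"
        )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    genic = np.zeros(m, dtype=bool)
    genic[rng.choice(m, size=int(round(genic_fraction * m)), replace=False)] = True

    # nested construction: permute once, then the set below each threshold
    # is a prefix of the permutation; p-values are drawn uniformly inside
    # the band its tightest satisfied threshold implies
    order = rng.permutation(m)
    counts = [int(round(f * m)) for f in fracs]  # loosest -> tightest
    eqtl_p = np.empty(m)
    # band edges from 0 up to 1: (0, thr_tightest], ..., (thr_loosest, 1]
    edges = [0.0] + sorted(thresholds) + [1.0]
    sizes = list(reversed(counts)) + [m]  # prefix lengths, tightest -> all
    prev_len = 0
    for (lo, hi), length in zip(zip(edges, edges[1:]), sizes):
        sel = order[prev_len:length]
        eqtl_p[sel] = rng.uniform(lo, hi, size=len(sel))
        prev_len = length

    df = pd.DataFrame({"snp": snp_ids, "genic": genic, "eqtl_p": eqtl_p})
    for thr in thresholds:
        df[f"eqtl_{thr:g}"] = df["eqtl_p"] < thr
    return df


def simulate_case_control_cohort(
    config: SimConfig,
    partition: dict[str, np.ndarray] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, SimTruth]:
    """Simulate a super-population and ascertain to the target case fraction.

    The super-population is sized so the expected case yield under the
    population prevalence K comfortably exceeds the quota (at least 20x
    the cohort when K is small), then exactly
    ``round(n_samples * target_case_fraction)`` cases and the matching
    number of controls are drawn.  Returns the ascertained genotypes,
    0/1 status labels, and the SimTruth of the super-population run
    (liability/score vectors subset to the ascertained samples).
    """
    P, K = config.target_case_fraction, config.prevalence_K
    need_factor = max(P / K, (1 - P) / (1 - K))
    super_n = int(np.ceil(config.n_samples * need_factor * 1.35))
    super_cfg = SimConfig(**{**config.__dict__, "n_samples": super_n})
    geno = simulate_genotypes(super_cfg)
    labels, truth = simulate_liability_phenotype(geno, super_cfg, partition)
    idx = ascertain_case_control(labels, P, seed=config.seed + 1, n_total=config.n_samples)
    cohort = geno.subset(sample_idx=idx)
    cohort.samples["status"] = labels[idx]
    truth.liability = truth.liability[idx]
    truth.genetic_score = truth.genetic_score[idx]
    return cohort, labels[idx].astype(np.int8), truth


def write_cohort(
    geno: GenotypeMatrix,
    truth: SimTruth,
    prefix: str | Path,
    annotations: pd.DataFrame | None = None,
) -> None:
    """Write PLINK bed/bim/fam, phenotype/covariate tables, annotation TSV
    and the SimTruth JSON sidecar under a common prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_plink(geno, prefix)
    s = geno.samples
    pheno = pd.DataFrame({"fid": s["fid"], "iid": s["iid"], "status": s.get("status", -9)})
    pheno.to_csv(f"{prefix}.pheno", sep=" ", index=False)
    covar_cols = {"fid": s["fid"], "iid": s["iid"]}
    for col in ("age", "sex", "skin_color"):
        if col in s:
            covar_cols[col] = s[col]
    pd.DataFrame(covar_cols).to_csv(f"{prefix}.covar", sep=" ", index=False)
    if annotations is not None:
        annotations.to_csv(f"{prefix}.annot.tsv", sep="\t", index=False)
    truth.to_json(f"{prefix}.truth.json")
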
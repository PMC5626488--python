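"""Genetic-architecture analyses built on GRM partitioning and joint REML.

These orchestration routines answer where heritability lives: per
chromosome (with a heritability-vs-chromosome-length regression that
flags chromosomes carrying more signal than their size predicts), per
MAF bin (allelic-spectrum partition), under a rare-variant model (subset
GRM calibrated against the full panel), and after excluding a region or
conditioning on an index SNP.  Joint multi-GRM fits keep the partition
additive: each partition's observed-scale h2 values are estimated
simultaneously, so their sum is comparable to the single-GRM estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gremlite.grm import (
    MAF_BIN_LABELS,
    adjust_grm,
    compute_grm,
    estimate_adjustment_c,
    partition_snps,
)
from gremlite.io import GenotypeMatrix
from gremlite.reml import LiabilityParams, VarianceComponentFit, fit_reml

__all__ = [
    "PartitionH2Table",
    "RegressionSummary",
    "per_chromosome_h2",
    "h2_length_regression",
    "maf_bin_h2",
    "rare_variant_model_h2",
    "region_exclude_or_condition",
    "chromosome_lengths",
]


@dataclass
class PartitionH2Table:
    """Per-label heritability estimates from one joint fit."""

    scheme: str
    table: pd.DataFrame  # label, n_snps, sigma2, se, h2_obs, h2_obs_se, h2_liab
    fit: VarianceComponentFit
    joint: bool = True  # False when the joint fit failed and labels were fit sequentially
    provenance: dict = field(default_factory=dict)


def _joint_partition_fit(
    geno: GenotypeMatrix,
    phenotype,
    covariates,
    spec,
    liability: LiabilityParams | None,
    scheme: str,
) -> PartitionH2Table:
    labels = [lab for lab in spec.label_universe if len(spec.snp_ids(lab)) > 0]
    dropped = [lab for lab in spec.label_universe if lab not in labels]
    if dropped:
        warnings.warn(f"empty partition label(s) dropped: {dropped}")
    if len(labels) == 1:
        warnings.warn(
            f"all SNPs fall in one {scheme} label; degenerating to a single-GRM fit"
        )
    grms = [compute_grm(geno, snp_subset=np.asarray(spec.snp_ids(lab))) for lab in labels]
    joint = True
    try:
        fit = fit_reml(
            phenotype,
            covariates,
            grms,
            component_names=labels,
            liability=liability,
        )
        if not fit.converged:
            raise RuntimeError("joint fit did not converge")
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        warnings.warn(
            f"joint {scheme} fit failed ({exc}); falling back to sequential "
            "single-GRM fits — per-label estimates are no longer jointly adjusted"
        )
        joint = False
        fit = None
        rows = []
        for lab, grm in zip(labels, grms):
            f = fit_reml(phenotype, covariates, [grm], component_names=[lab], liability=liability)
            rows.append(f)
        fit = rows[0]
        table = pd.DataFrame(
            {
                "label": labels,
                "n_snps": [g.n_snps for g in grms],
                "sigma2": [f.variances[0] for f in rows],
                "se": [f.se[0] for f in rows],
                "h2_obs": [f.h2_obs[0] for f in rows],
                "h2_obs_se": [f.h2_obs_se[0] for f in rows],
            }
        )
        if liability is not None:
            table["h2_liab"] = [f.h2_liab[0] for f in rows]
            table["h2_liab_se"] = [f.h2_liab_se[0] for f in rows]
        return PartitionH2Table(scheme=scheme, table=table, fit=fit, joint=False)

    table = pd.DataFrame(
        {
            "label": labels,
            "n_snps": [g.n_snps for g in grms],
            "sigma2": fit.variances[:-1],
            "se": fit.se[:-1],
            "h2_obs": fit.h2_obs,
            "h2_obs_se": fit.h2_obs_se,
        }
    )
    if liability is not None:
        table["h2_liab"] = fit.h2_liab
        table["h2_liab_se"] = fit.h2_liab_se
    return PartitionH2Table(scheme=scheme, table=table, fit=fit, joint=joint)


def per_chromosome_h2(
    geno: GenotypeMatrix,
    phenotype,
    covariates,
    liability_params: LiabilityParams | None = None,
) -> PartitionH2Table:
    """One GRM per chromosome, fit simultaneously in a single joint REML.

    Requires at least two chromosomes.  On joint non-convergence the
    routine falls back to sequential per-chromosome fits and flags the
    result (``joint = False``).
    """
    spec = partition_snps(geno.snps, "chromosome")
    if len(spec.label_universe) < 2:
        raise ValueError("per-chromosome analysis needs >= 2 chromosomes")
    return _joint_partition_fit(
        geno, phenotype, covariates, spec, liability_params, "chromosome"
    )


def chromosome_lengths(geno: GenotypeMatrix) -> pd.Series:
    """Base-pair span of genotyped SNPs per chromosome (max - min position)."""
    g = geno.snps.groupby(geno.snps["chrom"].astype(str))["pos"]
    return (g.max() - g.min()).astype(float)


@dataclass
class RegressionSummary:
    """OLS of per-chromosome h2 on chromosome length with outlier calls."""

    slope: float
    intercept: float
    r: float
    p_value: float
    slope_se: float
    conf_level: float
    table: pd.DataFrame  # label, length, h2, fitted, lo, hi, outside
    outliers: list[str]


def h2_length_regression(
    h2_table: pd.DataFrame,
    lengths: pd.Series,
    conf_level: float = 0.95,
    value_col: str = "h2_obs",
) -> RegressionSummary:
    """Regress per-chromosome h2 on physical length; flag outliers.

    Under a polygenic model heritability is proportional to chromosome
    size; chromosomes outside the pointwise ``conf_level`` confidence
    band of the fitted line carry disproportionate signal.  The band is
    derived from the slope/intercept covariance of the OLS fit.
    """
    merged = h2_table.set_index("label")[value_col].to_frame("h2")
    merged["length"] = pd.Series(lengths).reindex(merged.index)
    if merged["length"].isna().any():
        missing = merged.index[merged["length"].isna()].tolist()
        raise ValueError(f"no length for chromosome(s) {missing}")
    if len(merged) < 3:
        raise ValueError("need at least 3 chromosomes for the regression")
    x = merged["length"].to_numpy()
    yv = merged["h2"].to_numpy()
    if np.var(x) == 0:
        raise ValueError("zero variance in chromosome lengths")

    res = stats.linregress(x, yv)
    n = len(x)
    fitted = res.intercept + res.slope * x
    resid = yv - fitted
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_line = np.sqrt(s2 * (1.0 / n + (x - x.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof)
    lo = fitted - tcrit * se_line
    hi = fitted + tcrit * se_line
    outside = (yv < lo) | (yv > hi)

    table = pd.DataFrame(
        {
            "label": merged.index,
            "length": x,
            "h2": yv,
            "fitted": fitted,
            "lo": lo,
            "hi": hi,
            "outside": outside,
        }
    ).reset_index(drop=True)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope_se=float(res.stderr),
        conf_level=conf_level,
        table=table,
        outliers=table.loc[table["outside"], "label"].tolist(),
    )


def maf_bin_h2(
    geno: GenotypeMatrix,
    phenotype,
    covariates,
    liability_params: LiabilityParams | None = None,
) -> PartitionH2Table:
    """Joint fit over the six MAF-bin GRMs (empty bins dropped with warning)."""
    spec = partition_snps(geno.snps, "maf_bin", maf=geno.maf())
    assert spec.label_universe == MAF_BIN_LABELS
    return _joint_partition_fit(geno, phenotype, covariates, spec, liability_params, "maf_bin")


@dataclass
class RareVariantFit:
    """Calibrated rare-variant-model heritability."""

    fit: VarianceComponentFit
    beta: float
    c: float
    c_raw: float
    n_snps_subset: int
    maf_ceiling: float


def rare_variant_model_h2(
    geno: GenotypeMatrix,
    phenotype,
    covariates,
    maf_ceiling: float,
    liability_params: LiabilityParams | None = None,
) -> RareVariantFit:
    """Heritability under the assumption that causal variants have
    MAF <= ``maf_ceiling``.

    A GRM from the low-MAF subset imperfectly tags the assumed causal
    variants; its prediction error is calibrated by regressing the
    subset GRM on the full-panel GRM, estimating the attenuation
    constant c, rescaling the subset GRM, and re-running REML.  The
    ceiling is a required explicit parameter.
    """
    if not 0 < maf_ceiling <= 0.5:
        raise ValueError("maf_ceiling must be in (0, 0.5]")
    maf = geno.maf()
    subset = np.flatnonzero(maf <= maf_ceiling)
    if len(subset) == 0:
        raise ValueError(f"no SNPs with MAF <= {maf_ceiling}")
    grm_full = compute_grm(geno)
    grm_subset = compute_grm(geno, snp_subset=subset)
    cal = estimate_adjustment_c(grm_subset, grm_full)
    adjusted = adjust_grm(grm_subset, cal.c)
    fit = fit_reml(
        phenotype,
        covariates,
        [adjusted],
        component_names=[f"maf<={maf_ceiling:g}"],
        liability=liability_params,
    )
    return RareVariantFit(
        fit=fit,
        beta=cal.beta,
        c=cal.c,
        c_raw=cal.c_raw,
        n_snps_subset=len(subset),
        maf_ceiling=maf_ceiling,
    )


def region_exclude_or_condition(
    geno: GenotypeMatrix,
    phenotype,
    covariates,
    region: tuple[str, int, int] | None = None,
    snp_id: str | None = None,
    mode: str = "exclude",
    liability_params: LiabilityParams | None = None,
) -> VarianceComponentFit:
    """Re-estimate h2 after dropping a region or conditioning on a SNP.

    ``mode='exclude'`` removes every SNP inside ``region`` (chromosome,
    start, end; 1-based inclusive) from the GRM; ``mode='condition'``
    keeps the GRM intact and adds the named SNP's dosage as a fixed
    covariate (missing calls mean-imputed for the covariate only).  The
    fit's ``provenance`` entry in ``component_names`` records which.
    """
    if mode not in ("exclude", "condition"):
        raise ValueError("mode must be 'exclude' or 'condition'")
    if mode == "exclude":
        if region is None:
            raise ValueError("exclude mode requires a region")
        chrom, start, end = region
        inside = (
            (geno.snps["chrom"].astype(str) == str(chrom))
            & (geno.snps["pos"] >= start)
            & (geno.snps["pos"] <= end)
        ).to_numpy()
        keep = np.flatnonzero(~inside)
        grm = compute_grm(geno, snp_subset=keep)
        name = f"all_minus_{chrom}:{start}-{end}"
        X = covariates
    else:
        if snp_id is None:
            raise ValueError("condition mode requires snp_id")
        j = geno.snp_index(snp_id)  # raises KeyError when absent
        dose = geno.X[:, j].astype(np.float64)
        dose[dose < 0] = np.nan
        dose = np.where(np.isfinite(dose), dose, np.nanmean(dose))
        if covariates is None:
            X = dose[:, None]
        elif isinstance(covariates, pd.DataFrame):
            X = covariates.assign(**{f"dose_{snp_id}": dose})
        else:
            X = np.column_stack([np.asarray(covariates), dose])
        grm = compute_grm(geno)
        name = f"all_conditioned_on_{snp_id}"
    return fit_reml(
        phenotype, X, [grm], component_names=[name], liability=liability_params
    )
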
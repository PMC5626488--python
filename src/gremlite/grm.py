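"""Genetic relatedness matrices: construction, calibration, partitioning, PCA.

The GRM entry for individuals j and k is the average over SNPs of
standardized-dosage products,

    A_jk = (1/N_jk) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with allele frequencies p_i estimated from the analysis sample and the
sum restricted to SNPs non-missing in both members (N_jk recorded per
pair).  When the GRM is built from a filtered SNP subset, imperfect LD
between genotyped and causal variants attenuates relatedness estimates;
the calibration constant c is recovered from the regression of the
subset GRM on the full-panel GRM via

    beta = 1 - (c + 1/N) * var(A_jk)        (off-diagonal pairs)

and the GRM rescaled accordingly before REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gremlite.io import AUTOSOMES, GenotypeMatrix, GRMatrix

__all__ = [
    "MAF_BINS",
    "PartitionSpec",
    "PCAResult",
    "compute_grm",
    "estimate_adjustment_c",
    "adjust_grm",
    "partition_snps",
    "pca",
]

# right-closed MAF bins; the first is left-closed at the QC floor 0.01
MAF_BINS = (
    (0.01, 0.05),
    (0.05, 0.1),
    (0.1, 0.2),
    (0.2, 0.3),
    (0.3, 0.4),
    (0.4, 0.5),
)


def _maf_bin_label(lo: float, hi: float) -> str:
    return f"({lo:g},{hi:g}]"


MAF_BIN_LABELS = tuple(_maf_bin_label(lo, hi) for lo, hi in MAF_BINS)


@dataclass
class PartitionSpec:
    """Disjoint labelling of SNPs under one scheme.

    ``labels`` maps SNP id -> label for every labelled SNP; SNPs the
    scheme does not cover (e.g. un-annotated SNPs under the eQTL scheme)
    are simply absent.  ``missing_inputs`` counts scheme inputs (listed
    SNPs) that were not found in the panel.
    """

    scheme: str
    labels: pd.Series
    label_universe: tuple[str, ...]
    missing_inputs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        extra = set(self.labels.unique()) - set(self.label_universe)
        if extra:
            raise ValueError(f"labels outside universe: {sorted(extra)}")

    def snp_ids(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in self.label_universe}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.labels.index, "scheme": self.scheme, "label": self.labels.values}
        )


def compute_grm(geno: GenotypeMatrix, snp_subset=None) -> GRMatrix:
    """Build the GRM from (a subset of) the panel.

    ``snp_subset`` may be SNP ids, integer indices, or a boolean mask.
    Missing genotypes are handled pairwise-complete: a SNP contributes to
    A_jk only when called in both j and k, and each pair's divisor N_jk
    counts exactly those SNPs.  Monomorphic SNPs in the subset are an
    error (zero frequency variance), named in the message.
    """
    idx = _resolve_subset(geno, snp_subset)
    if geno.n < 2:
        raise ValueError("GRM needs at least 2 samples")
    if len(idx) == 0:
        raise ValueError("empty SNP subset")
    X = geno.X[:, idx].astype(np.float64)
    obs = X >= 0
    X[~obs] = np.nan
    counts = obs.sum(axis=0)
    p = np.nansum(X, axis=0) / (2.0 * counts)
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        names = geno.snps["snp"].iloc[idx[mono]].tolist()
        raise ValueError(f"monomorphic SNP(s) in GRM subset: {names[:5]}")
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z[~obs] = 0.0
    M = obs.astype(np.float64)
    N = M @ M.T
    if (N == 0).any():
        raise ValueError("some sample pairs share no non-missing SNPs")
    A = (Z @ Z.T) / N
    return GRMatrix(ids=geno.sample_ids.tolist(), A=A, N=N, n_snps=len(idx))


def _resolve_subset(geno: GenotypeMatrix, snp_subset) -> np.ndarray:
    if snp_subset is None:
        return np.arange(geno.m)
    arr = np.asarray(snp_subset)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        return arr
    lookup = pd.Index(geno.snps["snp"])
    pos = lookup.get_indexer(arr)
    if (pos < 0).any():
        missing = arr[pos < 0][:5].tolist()
        raise KeyError(f"SNPs not in panel: {missing}")
    return pos


@dataclass
class AdjustmentCalibration:
    """Result of regressing a subset GRM on the full GRM."""

    beta: float
    c: float
    c_raw: float
    var_offdiag: float
    n_snps: int


def estimate_adjustment_c(
    grm_subset: GRMatrix, grm_full: GRMatrix, n_snps_full: int | None = None
) -> AdjustmentCalibration:
    """Estimate the LD-attenuation constant c.

    beta is the slope of subset off-diagonals G_jk regressed on full
    off-diagonals A_jk, and c = (1 - beta)/var(A_jk) - 1/N with N the
    full-panel SNP count.  Sampling noise can push c slightly negative;
    it is then clamped to 0 with a warning (the raw value is kept).
    """
    if grm_subset.ids != grm_full.ids:
        raise ValueError("GRMs must cover identical samples in identical order")
    N = grm_full.n_snps if n_snps_full is None else n_snps_full
    a = grm_full.offdiag()
    g = grm_subset.offdiag()
    var_a = float(np.var(a))
    if var_a == 0:
        raise ValueError("full GRM has zero off-diagonal variance")
    beta = float(np.cov(a, g, ddof=0)[0, 1] / var_a)
    c_raw = (1.0 - beta) / var_a - 1.0 / N
    c = c_raw
    if c < 0:
        warnings.warn(f"estimated c = {c_raw:.3g} < 0 (sampling noise); clamped to 0")
        c = 0.0
    return AdjustmentCalibration(beta=beta, c=c, c_raw=c_raw, var_offdiag=var_a, n_snps=N)


def adjust_grm(grm: GRMatrix, c: float) -> GRMatrix:
    """Rescale a GRM for the prediction error of imperfect tagging.

    A GRM built from a filtered SNP panel predicts relatedness at the
    (unobserved) causal loci with error, which attenuates the fitted
    genetic variance downward.  The correction multiplies off-diagonals
    by the predicted attenuation slope

        scale = beta = 1 - (c + 1/N) * var(A_jk)   (0 < scale <= 1)

    and maps diagonals as A*_jj = 1 + (A_jj - 1) * scale; shrinking the
    off-diagonals raises the REML genetic variance by ~1/scale, undoing
    the downward bias.  c = 0 is the exact identity.  Re-adjusting an
    already adjusted GRM is refused.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    if grm.adjusted:
        raise ValueError("GRM already adjusted; re-adjustment is not meaningful")
    out = GRMatrix(
        ids=list(grm.ids),
        A=grm.A.copy(),
        N=grm.N.copy(),
        n_snps=grm.n_snps,
        calibration={**grm.calibration, "adjusted": True, "c": c},
    )
    if c == 0:
        out.calibration["scale"] = 1.0
        return out
    var_a = float(np.var(grm.offdiag()))
    scale = 1.0 - (c + 1.0 / grm.n_snps) * var_a
    if scale <= 0:
        raise ValueError(f"pathological c: attenuation scale {scale} <= 0")
    diag = np.diag(out.A).copy()
    out.A *= scale
    np.fill_diagonal(out.A, 1.0 + (diag - 1.0) * scale)
    out.calibration["scale"] = scale
    return out


def partition_snps(
    snps: pd.DataFrame,
    scheme: str,
    *,
    maf: np.ndarray | None = None,
    annotation: pd.DataFrame | None = None,
    eqtl_threshold: float | None = None,
    snp_list=None,
    window_kb: float | None = None,
) -> PartitionSpec:
    """Label SNPs under one partition scheme.

    Schemes: ``chromosome`` (one label per autosome present), ``maf_bin``
    (the six bins (0.01,0.05] .. (0.4,0.5]; requires ``maf``), ``genic``
    (requires ``annotation`` with a boolean ``genic`` column),
    ``eqtl_threshold`` (requires ``annotation`` with ``eqtl_p`` and an
    ``eqtl_threshold``; only annotated SNPs are labelled), and
    ``snp_list_region`` (SNPs within ``window_kb`` up/downstream of any
    listed SNP's position, same chromosome; listed SNPs absent from the
    panel are counted in ``missing_inputs``).
    """
    snp_ids = snps["snp"]
    if scheme == "chromosome":
        auto = snps["chrom"].astype(str).isin(AUTOSOMES)
        labels = pd.Series(snps["chrom"].astype(str).values, index=snp_ids)[auto.values]
        universe = tuple(sorted(labels.unique(), key=int))
        return PartitionSpec("chromosome", labels, universe)

    if scheme == "maf_bin":
        if maf is None:
            raise ValueError("maf_bin scheme requires per-SNP MAF values")
        maf = np.asarray(maf, dtype=float)
        labels = pd.Series(pd.NA, index=snp_ids, dtype=object)
        for (lo, hi), lab in zip(MAF_BINS, MAF_BIN_LABELS):
            sel = (maf <= hi) & ((maf > lo) if lab != MAF_BIN_LABELS[0] else (maf >= lo))
            labels.iloc[np.flatnonzero(sel)] = lab
        dropped = int(labels.isna().sum())
        if dropped:
            warnings.warn(f"{dropped} SNPs outside [0.01, 0.5] left unlabelled")
        return PartitionSpec("maf_bin", labels.dropna(), MAF_BIN_LABELS)

    if scheme == "genic":
        if annotation is None or "genic" not in annotation:
            raise ValueError("genic scheme requires annotation with a 'genic' column")
        ann = annotation.set_index("snp")["genic"].reindex(snp_ids)
        labels = ann.map({True: "genic", False: "intergenic", 1.0: "genic", 0.0: "intergenic"})
        return PartitionSpec("genic", labels.dropna(), ("genic", "intergenic"))

    if scheme == "eqtl_threshold":
        if annotation is None or "eqtl_p" not in annotation or eqtl_threshold is None:
            raise ValueError("eqtl scheme requires annotation 'eqtl_p' and a threshold")
        pvals = annotation.set_index("snp")["eqtl_p"].reindex(snp_ids)
        labels = pvals.dropna().map(lambda p: "eqtl" if p < eqtl_threshold else "non_eqtl")
        return PartitionSpec(f"eqtl_{eqtl_threshold:g}", labels, ("eqtl", "non_eqtl"))

    if scheme == "snp_list_region":
        if snp_list is None or window_kb is None:
            raise ValueError("region scheme requires snp_list and window_kb")
        window = int(window_kb * 1000)
        pos_by_id = snps.set_index("snp")
        missing = [s for s in snp_list if s not in pos_by_id.index]
        anchors = pos_by_id.loc[[s for s in snp_list if s in pos_by_id.index]]
        in_region = np.zeros(len(snps), dtype=bool)
        for _, row in anchors.iterrows():
            same = (snps["chrom"].astype(str) == str(row["chrom"])).to_numpy()
            near = (snps["pos"].to_numpy() >= row["pos"] - window) & (
                snps["pos"].to_numpy() <= row["pos"] + window
            )
            in_region |= same & near
        labels = pd.Series(np.where(in_region, "region", "background"), index=snp_ids)
        return PartitionSpec("snp_list_region", labels, ("region", "background"), missing)

    raise ValueError(
        f"unknown scheme {scheme!r}; valid: chromosome, maf_bin, genic, "
        "eqtl_threshold, snp_list_region"
    )


@dataclass
class PCAResult:
    """Top-k principal components of the GRM with generic outlier flags."""

    components: np.ndarray  # n x k unit-norm eigenvectors, descending eigenvalue
    eigenvalues: np.ndarray
    outlier: np.ndarray  # True when > 6 SD from the mean on PC1 or PC2
    degenerate: bool


def pca(grm: GRMatrix, k: int, outlier_sd: float = 6.0) -> PCAResult:
    """Eigendecomposition of the GRM; the standard stratification PCs.

    Component signs are fixed by making each component's
    largest-magnitude loading positive.  A sample is flagged as an
    ancestry outlier when it lies more than ``outlier_sd`` standard
    deviations from the mean on either of the top two PCs.  When the
    spectrum is (near-)flat — an identity-like GRM carries no structure —
    the ``degenerate`` flag is raised.
    """
    n = grm.n
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    all_vals, vecs = np.linalg.eigh(grm.A)
    order = np.argsort(all_vals)[::-1][:k]
    vals = all_vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    spread = float(np.ptp(all_vals))
    degenerate = bool(spread < 1e-8 * max(1.0, abs(vals[0])))
    outlier = np.zeros(n, dtype=bool)
    for j in range(min(2, k)):
        pc = vecs[:, j]
        sd = pc.std()
        if sd > 0:
            outlier |= np.abs(pc - pc.mean()) > outlier_sd * sd
    return PCAResult(components=vecs, eigenvalues=vals, outlier=outlier, degenerate=degenerate)
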
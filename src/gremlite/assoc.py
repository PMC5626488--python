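"""Per-SNP covariate-adjusted logistic-regression GWAS.

Each SNP is tested with an additive 0/1/2 genotype term in a logistic
model for case/control status alongside the fixed covariates (typically
age, sex and the leading ancestry PCs; optionally the ordinal 1-10 skin
color).  Fitting is full maximum likelihood via Newton iterations run
batched across SNPs, with per-SNP missing-genotype masks, so a scan of
the whole panel costs a handful of vectorised passes rather than one
model fit per SNP — this is what makes label-permutation enrichment
tests (1,000 re-scans) practical.

P-values are two-sided Wald tests; SNPs with (quasi-)separated or
non-converged likelihoods are flagged and reported with a score-test
fallback p-value rather than a fabricated Wald value.  The scan reports
the genomic inflation factor lambda = median(chi2) / 0.4549.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from gremlite.io import GenotypeMatrix

__all__ = ["AssocTable", "gwas_logistic", "stratified_gwas"]

_CHI2_NULL_MEDIAN = 0.4549364231195724  # chi2(1).ppf(0.5)
GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

_MAX_ABS_BETA = 15.0  # |log-odds| beyond this is treated as separation


@dataclass
class AssocTable:
    """Per-SNP association results plus scan metadata.

    ``table`` columns: snp, chrom, pos, a1, freq, beta (log-odds per A1
    allele), se, or_, p, chi2, n, n_missing, flag ('' | 'monomorphic' |
    'separation' | 'not_converged').  Flagged SNPs carry NaN beta/se and,
    where computable, a score-test p in ``p_score``.
    """

    table: pd.DataFrame
    lambda_gc: float
    covariate_names: list[str]
    n_samples: int
    n_dropped: int = 0

    def top(self, k: int) -> pd.DataFrame:
        """Top-k rows by ascending p, ties broken by larger |beta| then SNP id."""
        t = self.table.copy()
        t["_abs_beta"] = -t["beta"].abs().fillna(0.0)
        t = t.sort_values(["p", "_abs_beta", "snp"], na_position="last")
        return t.drop(columns="_abs_beta").head(k)


def _newton_scan(y: np.ndarray, C: np.ndarray, G: np.ndarray, max_iter: int = 30):
    """Batched per-SNP logistic Newton solver.

    G is n x m float with NaN for missing calls.  Returns beta, se,
    converged mask, per-SNP effective n.  Samples missing a SNP drop out
    of that SNP's likelihood via zero weights.
    """
    n, q = C.shape
    m = G.shape[1]
    mask = np.isfinite(G)
    G0 = np.where(mask, G, 0.0)
    maskf = mask.astype(np.float64)

    theta = np.zeros((m, q + 1))  # covariate coefs then genotype coef
    # warm start at the pooled covariate-only fit
    theta[:, :q] = _null_fit(y, C, np.ones(n))[None, :]
    converged = np.zeros(m, dtype=bool)
    se_b = np.full(m, np.nan)

    active = np.arange(m)
    for _ in range(max_iter):
        Ga = G0[:, active]
        Ma = maskf[:, active]
        eta = C @ theta[active, :q].T + Ga * theta[active, q][None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu) * Ma
        resid = (y[:, None] - mu) * Ma
        s_cov = np.einsum("nk,ns->sk", C, resid)
        s_g = np.einsum("ns,ns->s", Ga, resid)
        H = np.empty((len(active), q + 1, q + 1))
        H[:, :q, :q] = np.einsum("ns,nk,nj->skj", w, C, C)
        H_gc = np.einsum("ns,nk->sk", w * Ga, C)
        H[:, q, :q] = H_gc
        H[:, :q, q] = H_gc
        H[:, q, q] = np.einsum("ns,ns->s", w, Ga * Ga)
        score = np.column_stack([s_cov, s_g])
        # ridge for numerically singular Hessians; flagged later
        H += 1e-10 * np.eye(q + 1)[None, :, :]
        delta = np.linalg.solve(H, score[:, :, None])[:, :, 0]
        theta[active] += delta
        done = np.max(np.abs(delta), axis=1) < 1e-8
        newly = active[done]
        converged[newly] = True
        if done.all():
            active = active[~done]
            break
        active = active[~done]
        if len(active) == 0:
            break

    # standard errors from the observed information at the solution
    eta = C @ theta[:, :q].T + G0 * theta[:, q][None, :]
    mu = expit(eta)
    w = mu * (1.0 - mu) * maskf
    H = np.empty((m, q + 1, q + 1))
    H[:, :q, :q] = np.einsum("ns,nk,nj->skj", w, C, C)
    H_gc = np.einsum("ns,nk->sk", w * G0, C)
    H[:, q, :q] = H_gc
    H[:, :q, q] = H_gc
    H[:, q, q] = np.einsum("ns,ns->s", w, G0 * G0)
    ok = converged & (np.abs(theta[:, q]) < _MAX_ABS_BETA)
    with np.errstate(invalid="ignore"):
        for idx in np.flatnonzero(ok):
            try:
                se_b[idx] = np.sqrt(np.linalg.inv(H[idx])[q, q])
            except np.linalg.LinAlgError:
                ok[idx] = False
    return theta[:, q], se_b, converged, ok, mask.sum(axis=0)


def _null_fit(y: np.ndarray, C: np.ndarray, weight: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Weighted covariate-only logistic fit (Newton)."""
    beta = np.zeros(C.shape[1])
    for _ in range(max_iter):
        mu = expit(C @ beta)
        w = mu * (1.0 - mu) * weight
        score = C.T @ ((y - mu) * weight)
        H = (C * w[:, None]).T @ C + 1e-10 * np.eye(C.shape[1])
        delta = np.linalg.solve(H, score)
        beta += delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    return beta


def _score_test(y: np.ndarray, C: np.ndarray, g: np.ndarray, mask: np.ndarray) -> float:
    """Score-test p for one SNP under the covariate-only null (fallback
    for separated SNPs, whose Wald statistic is meaningless)."""
    wmask = mask.astype(float)
    beta0 = _null_fit(y, C, wmask)
    mu = expit(C @ beta0)
    w = mu * (1 - mu) * wmask
    g0 = np.where(mask, g, 0.0)
    U = float(g0 @ ((y - mu) * wmask))
    CtWC = (C * w[:, None]).T @ C
    CtWg = C.T @ (w * g0)
    V = float(g0 @ (w * g0) - CtWg @ np.linalg.solve(CtWC, CtWg))
    if V <= 0:
        return np.nan
    return float(stats.chi2.sf(U * U / V, df=1))


def _build_design(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=np.float64)
    else:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"covar{j + 1}" for j in range(C.shape[1])]
    if np.any(~np.isfinite(C)):
        raise ValueError("covariates contain missing/non-finite values for included samples")
    if np.any(C.std(axis=0) == 0):
        bad = [names[j] for j in np.flatnonzero(C.std(axis=0) == 0)]
        raise ValueError(f"constant covariate(s): {bad}")
    return np.column_stack([np.ones(n), C]), ["intercept"] + names


def gwas_logistic(
    geno: GenotypeMatrix,
    status=None,
    covariates=None,
    include_skin_color: bool = False,
    skin_color=None,
    chunk_size: int = 2048,
) -> AssocTable:
    """Additive logistic GWAS over the panel.

    ``status`` defaults to the 0/1 status column of ``geno.samples``.
    With ``include_skin_color`` the ordinal skin-color covariate (from
    ``skin_color`` or ``geno.samples['skin_color']``) joins the model and
    samples missing it are dropped from this scan only, with the count
    reported in ``n_dropped``.
    """
    if status is None:
        if "status" not in geno.samples:
            raise ValueError("no status vector given and none in the genotype metadata")
        status = geno.samples["status"].to_numpy()
    y = np.asarray(status, dtype=np.float64)
    if set(np.unique(y[np.isfinite(y)])) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")

    keep = np.isfinite(y)
    n_dropped = 0
    sc = None
    if include_skin_color:
        if skin_color is None:
            if "skin_color" not in geno.samples:
                raise ValueError("skin-color model requested but no skin color available")
            skin_color = geno.samples["skin_color"].to_numpy()
        sc = np.asarray(skin_color, dtype=np.float64)
        n_dropped = int((keep & ~np.isfinite(sc)).sum())
        keep &= np.isfinite(sc)
    idx = np.flatnonzero(keep)
    y = y[idx]
    n = len(idx)

    if isinstance(covariates, pd.DataFrame):
        cov = covariates.iloc[idx]
    elif covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[idx]
    else:
        cov = None
    if include_skin_color:
        sc_col = pd.Series(sc[idx], name="skin_color")
        if cov is None:
            cov = sc_col.to_frame()
        elif isinstance(cov, pd.DataFrame):
            cov = cov.reset_index(drop=True).assign(skin_color=sc_col.values)
        else:
            cov = pd.DataFrame(
                np.column_stack([cov, sc[idx]]),
                columns=[f"covar{j + 1}" for j in range(np.atleast_2d(cov).shape[1])]
                + ["skin_color"],
            )
    C, cov_names = _build_design(cov, n)

    m = geno.m
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pvals = np.full(m, np.nan)
    p_score = np.full(m, np.nan)
    flags = np.array([""] * m, dtype=object)
    n_eff = np.zeros(m, dtype=int)

    Xsub = geno.X[idx]
    for start in range(0, m, chunk_size):
        stop = min(start + chunk_size, m)
        G = Xsub[:, start:stop].astype(np.float64)
        G[G < 0] = np.nan
        obs = np.isfinite(G)
        counts = obs.sum(axis=0)
        freq = np.nansum(G, axis=0) / np.maximum(2.0 * counts, 1.0)
        mono = (freq <= 0) | (freq >= 1) | (counts == 0)
        cols = np.arange(start, stop)
        flags[cols[mono]] = "monomorphic"
        n_eff[cols] = counts
        live = ~mono
        if not live.any():
            continue
        b, s, conv, ok, _ = _newton_scan(y, C, G[:, live])
        live_cols = cols[live]
        beta[live_cols] = np.where(ok, b, np.nan)
        se[live_cols] = s
        pvals[live_cols] = np.where(ok, 2.0 * stats.norm.sf(np.abs(b / s)), np.nan)
        bad = ~ok
        for local_i in np.flatnonzero(bad):
            col = live_cols[local_i]
            flags[col] = "separation" if np.abs(b[local_i]) >= _MAX_ABS_BETA else "not_converged"
            gcol = G[:, live][:, local_i]
            p_score[col] = _score_test(y, C, np.nan_to_num(gcol), np.isfinite(gcol))

    freq_all = np.full(m, np.nan)
    obs_all = Xsub >= 0
    cnt = obs_all.sum(axis=0)
    freq_all = np.where(cnt > 0, np.where(obs_all, Xsub, 0).sum(axis=0) / (2.0 * cnt), np.nan)

    chi2 = (beta / se) ** 2
    valid = np.isfinite(chi2)
    lam = float(np.median(chi2[valid]) / _CHI2_NULL_MEDIAN) if valid.any() else np.nan

    table = pd.DataFrame(
        {
            "snp": geno.snps["snp"],
            "chrom": geno.snps["chrom"],
            "pos": geno.snps["pos"],
            "a1": geno.snps["a1"],
            "freq": freq_all,
            "beta": beta,
            "se": se,
            "or_": np.exp(beta),
            "p": pvals,
            "p_score": p_score,
            "chi2": chi2,
            "n": n_eff,
            "n_missing": n - n_eff,
            "flag": flags,
        }
    )
    return AssocTable(
        table=table,
        lambda_gc=lam,
        covariate_names=cov_names,
        n_samples=n,
        n_dropped=n_dropped,
    )


def stratified_gwas(
    geno: GenotypeMatrix,
    status=None,
    covariates=None,
    skin_color=None,
    light_range: tuple[int, int] = (1, 3),
    dark_range: tuple[int, int] = (4, 10),
) -> dict[str, AssocTable]:
    """Independent scans in light- and dark-skinned strata.

    The default split is skin color 1-3 (light) vs 4-10 (dark).  Samples
    without skin color are excluded; an empty stratum is an error.
    """
    if skin_color is None:
        if "skin_color" not in geno.samples:
            raise ValueError("stratified scan requires skin color")
        skin_color = geno.samples["skin_color"].to_numpy()
    sc = np.asarray(skin_color, dtype=np.float64)
    out: dict[str, AssocTable] = {}
    for name, (lo, hi) in (("light", light_range), ("dark", dark_range)):
        sel = np.isfinite(sc) & (sc >= lo) & (sc <= hi)
        if not sel.any():
            raise ValueError(f"empty {name} stratum (skin color {lo}-{hi})")
        sub = geno.subset(sample_idx=sel)
        st = None if status is None else np.asarray(status)[sel]
        if isinstance(covariates, pd.DataFrame):
            cov = covariates.loc[sel].reset_index(drop=True)
        elif covariates is not None:
            cov = np.asarray(covariates)[sel]
        else:
            cov = None
        out[name] = gwas_logistic(sub, status=st, covariates=cov)
    return out
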
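"""Variance-component estimation by average-information REML.

The mixed linear model is

    y = X b + g_1 + ... + g_R + e,
    var(y) = V = sum_r A_r sigma2_r + I sigma2_e,

with one random effect per GRM.  The restricted log-likelihood

    logL_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

is maximised over non-negative variance components by average-information
(AI) quasi-Newton updates, with expectation-maximisation steps for the
first iterations and as a fallback whenever an AI step would decrease the
likelihood.  Standard errors come from the inverse AI matrix at the
optimum, and per-component observed-scale heritabilities
h2_r = sigma2_r / sum(sigma2) carry delta-method standard errors.

For a single GRM the problem is rotated into the eigenbasis of the GRM
restricted to the orthogonal complement of X, where every REML quantity
is a sum over scalars; this is exact (same optimum, same likelihood, same
AI matrix) and makes permutation tests cheap because the rotation depends
only on (A, X), not on y.

Case-control traits analysed on the observed 0/1 scale are transformed to
the liability scale of the probit threshold model: with population
prevalence K, probit threshold t = Phi^-1(1 - K), z = phi(t), and sample
case fraction P under ascertainment,

    h2_liability = h2_observed * K^2 (1 - K)^2 / (z^2 P (1 - P)),

which reduces to the classic K(1-K)/z^2 factor when P = K and equals
pi/2 at the symmetric point K = P = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from gremlite.io import GRMatrix

__all__ = [
    "LiabilityParams",
    "VarianceComponentFit",
    "PermutationResult",
    "ConvergenceError",
    "IdentifiabilityError",
    "fit_reml",
    "observed_to_liability",
    "lrt_pvalue",
    "h2_permutation_test",
]


class IdentifiabilityError(ValueError):
    """Genetic and residual components cannot be separated."""


class ConvergenceError(RuntimeError):
    """REML failed to converge and the caller asked for strictness."""


@dataclass(frozen=True)
class LiabilityParams:
    """Probit-threshold quantities for the liability transform.

    K is the population prevalence, P the (possibly ascertained) sample
    case fraction.  The study regime this package was built around is
    K = 0.02, P = 0.66.
    """

    K: float
    P: float

    def __post_init__(self) -> None:
        if not 0 < self.K < 1 or not 0 < self.P < 1:
            raise ValueError(f"K and P must be in (0,1), got K={self.K}, P={self.P}")

    @property
    def threshold(self) -> float:
        return float(stats.norm.ppf(1.0 - self.K))

    @property
    def z(self) -> float:
        return float(stats.norm.pdf(self.threshold))

    @property
    def factor(self) -> float:
        K, P, z = self.K, self.P, self.z
        return (K * (1 - K)) ** 2 / (z * z * P * (1 - P))


def observed_to_liability(h2_obs: float, params: LiabilityParams) -> float:
    """Map an observed-scale (0/1) h2 to the liability scale."""
    if h2_obs < 0:
        raise ValueError("h2_obs must be >= 0")
    return h2_obs * params.factor


def lrt_pvalue(logL_full: float, logL_reduced: float, n_constrained_components: int = 1) -> float:
    """Boundary-corrected likelihood-ratio p-value for variance components.

    A variance tested at 0 sits on the parameter-space boundary, so the
    LRT statistic is a 50:50 mixture of a point mass at 0 and chi-square
    with 1 df (for one component): p = 0.5 * P(chi2_1 > Lambda).
    """
    lam = 2.0 * (logL_full - logL_reduced)
    if lam < -1e-6:
        raise ValueError(
            f"full-model logL below reduced-model logL (Lambda = {lam:.3g}); inconsistent fits"
        )
    lam = max(lam, 0.0)
    k = n_constrained_components
    if k == 1:
        return float(0.5 * stats.chi2.sf(lam, df=1))
    lower = 1.0 if k == 1 else stats.chi2.sf(lam, df=k - 1)
    return float(0.5 * (lower + stats.chi2.sf(lam, df=k)))


@dataclass
class VarianceComponentFit:
    """REML solution for one phenotype and one or more GRMs."""

    component_names: list[str]
    variances: np.ndarray  # genetic components then residual
    se: np.ndarray
    logL: float
    h2_obs: np.ndarray  # per genetic component
    h2_obs_se: np.ndarray
    fixed_effects: np.ndarray
    fixed_effects_se: np.ndarray
    converged: bool
    n_iter: int
    liability: LiabilityParams | None = None
    h2_liab: np.ndarray | None = None
    h2_liab_se: np.ndarray | None = None
    vcov_variances: np.ndarray | None = None

    @property
    def total_variance(self) -> float:
        return float(self.variances.sum())

    @property
    def h2_total(self) -> float:
        return float(self.h2_obs.sum())

    def summary(self) -> str:
        lines = ["component  sigma2      SE        h2_obs    h2_liab"]
        for i, name in enumerate(self.component_names[:-1]):
            liab = f"{self.h2_liab[i]:.4f}" if self.h2_liab is not None else "-"
            lines.append(
                f"{name:<10} {self.variances[i]:<11.5f}{self.se[i]:<10.5f}"
                f"{self.h2_obs[i]:<10.4f}{liab}"
            )
        lines.append(f"{'residual':<10} {self.variances[-1]:<11.5f}{self.se[-1]:<10.5f}")
        lines.append(f"logL = {self.logL:.4f}  converged = {self.converged} ({self.n_iter} it)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _design_matrix(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column whose addition does not raise the rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(j - 1)  # covariate index (column 0 is the intercept)
            r = rj
        raise ValueError(f"design matrix rank-deficient; collinear covariate column(s) {bad}")
    return X


def _coerce_grms(grms) -> list[np.ndarray]:
    if isinstance(grms, (GRMatrix, np.ndarray)):
        grms = [grms]
    mats = []
    for g in grms:
        A = g.A if isinstance(g, GRMatrix) else np.asarray(g, dtype=np.float64)
        mats.append(A)
    n = mats[0].shape[0]
    for A in mats:
        if A.shape != (n, n):
            raise ValueError("all GRMs must cover the same ordered samples")
    return mats


class _RotatedSingleGRM:
    """Single-GRM REML in the eigenbasis of B'AB (B = complement of X).

    Building the rotation costs one dense eigendecomposition; after that
    every REML iteration is O(n), and the rotation can be reused across
    phenotype vectors (the permutation tests rely on this).
    """

    def __init__(self, A: np.ndarray, X: np.ndarray):
        n, p = X.shape
        Q, _ = np.linalg.qr(X, mode="complete")
        B = Q[:, p:]
        M = B.T @ A @ B
        d, U = np.linalg.eigh(M)
        self.rotation = B @ U  # n x (n-p)
        self.d = d
        self.n = n
        self.p = p
        sign, logdet = np.linalg.slogdet(X.T @ X)
        self.logdet_XtX = logdet
        self.A = A
        self.X = X

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.rotation.T @ y

    def fit(self, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
        w = self.rotate(y)
        w2 = w * w
        d = self.d
        vp = float(np.var(y))
        floor = 1e-8 * vp
        sig = np.array([vp / 2.0, vp / 2.0])  # genetic, residual

        def logL(s):
            v = s[0] * d + s[1]
            if np.any(v <= 0):
                return -np.inf
            return -0.5 * (np.sum(np.log(v)) + np.sum(w2 / v) + self.logdet_XtX)

        ll = logL(sig)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            v = sig[0] * d + sig[1]
            inv_v = 1.0 / v
            quad_g = np.sum(d * w2 * inv_v**2)
            quad_e = np.sum(w2 * inv_v**2)
            tr_g = np.sum(d * inv_v)
            tr_e = np.sum(inv_v)
            score = 0.5 * np.array([quad_g - tr_g, quad_e - tr_e])
            ai = 0.5 * np.array(
                [
                    [np.sum(d * d * w2 * inv_v**3), np.sum(d * w2 * inv_v**3)],
                    [np.sum(d * w2 * inv_v**3), np.sum(w2 * inv_v**3)],
                ]
            )
            # components pinned at the floor with downhill score stay frozen
            free = ~((sig <= floor * (1 + 1e-12)) & (score < 0))
            if not free.any():
                converged = True
                break
            em_step = sig**2 * np.array([quad_g - tr_g, quad_e - tr_e]) / self.n
            if it <= 3:
                new = sig + np.where(free, em_step, 0.0)
            else:
                delta = np.zeros(2)
                try:
                    delta[free] = np.linalg.solve(
                        ai[np.ix_(free, free)], score[free]
                    )
                except np.linalg.LinAlgError:
                    delta = np.where(free, em_step, 0.0)
                new = sig + delta
                # step-halve if the AI step overshoots
                for _ in range(10):
                    if logL(np.maximum(new, floor)) >= ll - 1e-10:
                        break
                    new = sig + (new - sig) / 2.0
            new = np.maximum(new, floor)
            new_ll = logL(new)
            if abs(new_ll - ll) < tol and it > 3:
                sig, ll = new, new_ll
                converged = True
                break
            sig, ll = new, new_ll
        v = sig[0] * d + sig[1]
        inv_v = 1.0 / v
        ai = 0.5 * np.array(
            [
                [np.sum(d * d * w2 * inv_v**3), np.sum(d * w2 * inv_v**3)],
                [np.sum(d * w2 * inv_v**3), np.sum(w2 * inv_v**3)],
            ]
        )
        return sig, ai, ll, it, converged


def _dense_reml(y, X, mats, max_iter=100, tol=1e-8):
    n = len(y)
    R = len(mats)
    vp = float(np.var(y))
    floor = 1e-8 * vp
    sig = np.full(R + 1, vp / (R + 1))
    I = np.eye(n)
    comps = mats + [I]

    def decompose(s):
        V = s[-1] * I
        for r in range(R):
            V = V + s[r] * mats[r]
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Vinv = linalg.cho_solve(cho, I, check_finite=False)
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtVinvX)
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        Py = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return P, Py, ll

    P, Py, ll = decompose(sig)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = np.column_stack([comps[r] @ Py for r in range(R + 1)])
        PU = P @ U
        ai = 0.5 * (U.T @ PU)
        quad = Py @ U
        tr = np.array([np.sum(P * comps[r]) for r in range(R + 1)])
        score = 0.5 * (quad - tr)
        free = ~((sig <= floor * (1 + 1e-12)) & (score < 0))
        if not free.any():
            converged = True
            break
        em_step = sig**2 * (quad - tr) / n
        if it <= 3:
            new = sig + np.where(free, em_step, 0.0)
        else:
            delta = np.zeros(R + 1)
            try:
                delta[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                delta = np.where(free, em_step, 0.0)
            new = sig + delta
        new = np.maximum(new, floor)
        P_new, Py_new, ll_new = decompose(new)
        # fall back to a damped EM step when AI overshoots
        tries = 0
        while ll_new < ll - 1e-10 and tries < 8:
            new = sig + (new - sig) / 2.0
            new = np.maximum(new, floor)
            P_new, Py_new, ll_new = decompose(new)
            tries += 1
        if abs(ll_new - ll) < tol and it > 3:
            sig, P, Py, ll = new, P_new, Py_new, ll_new
            converged = True
            break
        sig, P, Py, ll = new, P_new, Py_new, ll_new
    U = np.column_stack([comps[r] @ Py for r in range(R + 1)])
    PU = P @ U
    ai = 0.5 * (U.T @ PU)
    return sig, ai, ll, it, converged


def _h2_with_se(sig: np.ndarray, vcov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method SEs for h2_r = sigma2_r / sum(sigma2)."""
    total = sig.sum()
    R = len(sig) - 1
    h2 = sig[:R] / total
    se = np.empty(R)
    for r in range(R):
        grad = np.full(len(sig), -sig[r] / total**2)
        grad[r] += 1.0 / total
        se[r] = np.sqrt(max(float(grad @ vcov @ grad), 0.0))
    return h2, se


def fit_reml(
    phenotype,
    fixed_covariates,
    grms,
    component_names: list[str] | None = None,
    liability: LiabilityParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponentFit:
    """AI-REML fit of one or more genetic variance components.

    ``phenotype`` is a length-n vector (binary 0/1 for case-control on
    the observed scale, or quantitative); ``fixed_covariates`` an
    n x q array or ``None`` (an intercept is always included); ``grms`` a
    GRMatrix / ndarray or a list of them over the same ordered samples.
    With ``liability`` set, per-component liability-scale h2 values and
    SEs are attached.  Non-convergence is flagged on the result, never
    silently dropped.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    mats = _coerce_grms(grms)
    if len(y) != mats[0].shape[0]:
        raise ValueError("phenotype length does not match GRM dimension")
    X = _design_matrix(len(y), fixed_covariates)
    n = len(y)
    eye = np.eye(n)
    if all(np.allclose(A, eye, atol=1e-8) for A in mats):
        raise IdentifiabilityError(
            "every GRM is (numerically) the identity; genetic and residual "
            "variance are not separable"
        )
    for r in range(len(mats)):
        for s in range(r + 1, len(mats)):
            if np.allclose(mats[r], mats[s], atol=1e-10):
                raise IdentifiabilityError(
                    f"GRM components {r} and {s} are numerically identical; "
                    "their variance components are collinear"
                )
    R = len(mats)
    if component_names is None:
        component_names = [f"G{r + 1}" for r in range(R)]
    if len(component_names) != R:
        raise ValueError("one component name per GRM required")

    if R == 1:
        model = _RotatedSingleGRM(mats[0], X)
        sig, ai, ll, it, converged = model.fit(y, max_iter=max_iter, tol=tol)
    else:
        sig, ai, ll, it, converged = _dense_reml(y, X, mats, max_iter=max_iter, tol=tol)

    try:
        vcov = np.linalg.inv(ai)
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    except np.linalg.LinAlgError:
        vcov = np.full((R + 1, R + 1), np.nan)
        se = np.full(R + 1, np.nan)

    h2, h2_se = _h2_with_se(sig, vcov)

    # fixed effects at the optimum
    V = sig[-1] * eye
    for r in range(R):
        V = V + sig[r] * mats[r]
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    VinvX = linalg.cho_solve(cho, X, check_finite=False)
    XtVinvX = X.T @ VinvX
    beta = np.linalg.solve(XtVinvX, VinvX.T @ y)
    beta_se = np.sqrt(np.diag(np.linalg.inv(XtVinvX)))

    fit = VarianceComponentFit(
        component_names=list(component_names) + ["residual"],
        variances=sig,
        se=se,
        logL=float(ll),
        h2_obs=h2,
        h2_obs_se=h2_se,
        fixed_effects=beta,
        fixed_effects_se=beta_se,
        converged=converged,
        n_iter=it,
        liability=liability,
        vcov_variances=vcov,
    )
    if liability is not None:
        fit.h2_liab = h2 * liability.factor
        fit.h2_liab_se = h2_se * liability.factor
    return fit


@dataclass
class PermutationResult:
    """Empirical significance of a subset-GRM heritability estimate."""

    observed_h2: float
    permuted_h2: np.ndarray
    p_value: float
    tie_rule: str
    n_failed: int
    effective_B: int
    seed: int


def h2_permutation_test(
    grm_subset,
    phenotype,
    fixed_covariates,
    n_permutations: int,
    seed: int,
    tie_rule: str = "inclusive",
    liability: LiabilityParams | None = None,
) -> PermutationResult:
    """Permutation significance for the h2 attributed to a SNP subset.

    Case/control labels are shuffled uniformly while covariates stay
    attached to their samples, REML is re-run per permutation (cheaply,
    by reusing the GRM eigenrotation), and the empirical p-value is the
    proportion of permutations whose h2 reaches the observed one —
    ties count as exceedances under the default ``inclusive`` rule;
    ``strict`` counts only h2 strictly above the observed value.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if tie_rule not in ("inclusive", "strict"):
        raise ValueError("tie_rule must be 'inclusive' or 'strict'")
    y = np.asarray(phenotype, dtype=np.float64)
    mats = _coerce_grms(grm_subset)
    if len(mats) != 1:
        raise ValueError("permutation test expects a single subset GRM")
    X = _design_matrix(len(y), fixed_covariates)
    model = _RotatedSingleGRM(mats[0], X)

    def h2_of(vec: np.ndarray) -> float:
        sig, _, _, _, _ = model.fit(vec)
        return float(sig[0] / sig.sum())

    observed = h2_of(y)
    rng = np.random.default_rng(seed)
    permuted = []
    n_failed = 0
    for _ in range(n_permutations):
        y_perm = y[rng.permutation(len(y))]
        try:
            permuted.append(h2_of(y_perm))
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
    permuted = np.asarray(permuted)
    if len(permuted) == 0:
        raise ConvergenceError("every permutation REML failed")
    if tie_rule == "inclusive":
        p = float(np.mean(permuted >= observed))
    else:
        p = float(np.mean(permuted > observed))
    return PermutationResult(
        observed_h2=observed,
        permuted_h2=permuted,
        p_value=p,
        tie_rule=tie_rule,
        n_failed=n_failed,
        effective_B=len(permuted),
        seed=seed,
    )
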
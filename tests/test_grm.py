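"""GRM construction, calibration, partition schemes and PCA."""

import numpy as np
import pandas as pd
import pytest

from gremlite.grm import (
    MAF_BIN_LABELS,
    adjust_grm,
    compute_grm,
    estimate_adjustment_c,
    partition_snps,
    pca,
)
from gremlite.io import GRMatrix
from gremlite.sim import SimConfig, simulate_genotypes
from tests.conftest import make_geno


def naive_grm(X):
    """Double-loop reference implementation with pairwise-complete sums."""
    X = X.astype(float)
    X[X < 0] = np.nan
    n, m = X.shape
    p = np.nanmean(X, axis=0) / 2.0
    A = np.zeros((n, n))
    N = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            s = 0.0
            cnt = 0
            for i in range(m):
                if np.isnan(X[j, i]) or np.isnan(X[k, i]):
                    continue
                s += (X[j, i] - 2 * p[i]) * (X[k, i] - 2 * p[i]) / (2 * p[i] * (1 - p[i]))
                cnt += 1
            A[j, k] = s / cnt
            N[j, k] = cnt
    return A, N


class TestComputeGRM:
    def test_single_snp_hand_values(self):
        # p = 0.5; x=1 gives 0 on the diagonal, (0,2) pair gives -2
        geno = make_geno(np.array([[0], [2], [1], [1]], dtype=np.int8))
        grm = compute_grm(geno)
        assert grm.A[2, 2] == pytest.approx(0.0)
        assert grm.A[0, 1] == pytest.approx(-2.0)
        assert grm.A[0, 0] == pytest.approx(2.0)  # (0-1)^2/0.5

    def test_matches_naive_reference_with_missing(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, rng.uniform(0.1, 0.5, 100), size=(20, 100)).astype(np.int8)
        X[rng.random(X.shape) < 0.05] = -1
        geno = make_geno(X)
        grm = compute_grm(geno)
        A_ref, N_ref = naive_grm(X.copy())
        assert np.abs(grm.A - A_ref).max() < 1e-10
        assert np.array_equal(grm.N, N_ref)

    def test_unrelated_moments(self):
        cfg = SimConfig(n_samples=50, n_snps=5000, maf_spec=(0.1, 0.5), seed=5)
        n, m = 50, 5000
        grm = compute_grm(simulate_genotypes(cfg))
        assert abs(np.diag(grm.A).mean() - 1.0) < 3.0 / np.sqrt(m)
        # in-sample allele frequencies centre each SNP column, which pins the
        # off-diagonal mean at -1/(n-1) rather than 0
        assert abs(grm.offdiag().mean() + 1.0 / (n - 1)) < 3.0 / np.sqrt(m * n)

    def test_monomorphic_snp_named_in_error(self):
        X = np.array([[0, 1], [0, 2], [0, 1]], dtype=np.int8)
        geno = make_geno(X, snp_ids=["mono1", "ok"])
        with pytest.raises(ValueError, match="mono1"):
            compute_grm(geno)

    def test_partition_pieces_recombine_by_snp_weighted_average(self):
        # complete data: GRM over a union = N-weighted average of the pieces
        rng = np.random.default_rng(6)
        X = rng.binomial(2, rng.uniform(0.2, 0.5, 60), size=(25, 60)).astype(np.int8)
        geno = make_geno(X)
        full = compute_grm(geno)
        a = compute_grm(geno, snp_subset=np.arange(0, 20))
        b = compute_grm(geno, snp_subset=np.arange(20, 60))
        combined = (20 * a.A + 40 * b.A) / 60
        assert np.abs(full.A - combined).max() < 1e-12


class TestCalibration:
    def _grm_pair(self, seed=7, n=40, m=600):
        cfg = SimConfig(n_samples=n, n_snps=m, maf_spec=(0.1, 0.5), seed=seed)
        geno = simulate_genotypes(cfg)
        full = compute_grm(geno)
        sub = compute_grm(geno, snp_subset=np.arange(m // 3))
        return full, sub

    def test_identity_regression_gives_beta_one_and_clamped_c(self):
        full, _ = self._grm_pair()
        with pytest.warns(UserWarning, match="clamped"):
            cal = estimate_adjustment_c(full, full)
        assert cal.beta == pytest.approx(1.0)
        assert cal.c == 0.0
        assert cal.c_raw == pytest.approx(-1.0 / full.n_snps)

    def test_constructed_slope_cancels_to_zero_c(self):
        full, _ = self._grm_pair(seed=8)
        var_a = np.var(full.offdiag())
        s = 1.0 - var_a / full.n_snps
        shrunk = GRMatrix(
            ids=list(full.ids), A=full.A * s, N=full.N, n_snps=full.n_snps
        )
        cal = estimate_adjustment_c(shrunk, full)
        assert cal.c_raw == pytest.approx(0.0, abs=1e-9)

    def test_subset_grm_yields_nonnegative_c(self):
        full, sub = self._grm_pair(seed=9)
        cal = estimate_adjustment_c(sub, full)
        assert cal.beta < 1.0
        assert cal.c >= 0.0

    def test_adjust_with_zero_c_is_identity(self):
        full, _ = self._grm_pair(seed=10)
        out = adjust_grm(full, 0.0)
        assert np.array_equal(out.A, full.A)
        assert out.adjusted

    def test_adjustment_shrinks_offdiagonals(self):
        # the attenuation correction scales |A_jk| down by beta < 1 so the
        # fitted genetic variance scales up
        full, _ = self._grm_pair(seed=11)
        out = adjust_grm(full, 5.0)
        iu = np.triu_indices(full.n, 1)
        assert np.all(np.abs(out.A[iu]) <= np.abs(full.A[iu]) + 1e-15)
        assert out.calibration["scale"] < 1.0

    def test_double_adjustment_refused(self):
        full, _ = self._grm_pair(seed=12)
        once = adjust_grm(full, 1.0)
        with pytest.raises(ValueError, match="already adjusted"):
            adjust_grm(once, 1.0)

    def test_pathological_c_rejected(self):
        full, _ = self._grm_pair(seed=13)
        var_a = np.var(full.offdiag())
        with pytest.raises(ValueError, match="pathological"):
            adjust_grm(full, 2.0 / var_a)

    def test_sample_mismatch_rejected(self):
        full, _ = self._grm_pair(seed=14)
        other = GRMatrix(
            ids=[f"x{i}" for i in range(full.n)], A=full.A, N=full.N, n_snps=full.n_snps
        )
        with pytest.raises(ValueError, match="identical samples"):
            estimate_adjustment_c(other, full)


class TestPartitionSchemes:
    def _snps(self, m=30):
        return pd.DataFrame(
            {
                "snp": [f"s{j}" for j in range(m)],
                "chrom": ["1"] * (m // 2) + ["2"] * (m - m // 2),
                "pos": list(range(1, m // 2 + 1)) + list(range(1, m - m // 2 + 1)),
                "a1": "A",
                "a2": "G",
            }
        )

    def test_maf_bin_boundaries_right_closed(self):
        snps = self._snps(4)
        maf = np.array([0.05, 0.050001, 0.2, 0.01])
        spec = partition_snps(snps, "maf_bin", maf=maf)
        assert spec.labels["s0"] == "(0.01,0.05]"
        assert spec.labels["s1"] == "(0.05,0.1]"
        assert spec.labels["s2"] == "(0.1,0.2]"
        assert spec.labels["s3"] == "(0.01,0.05]"  # QC floor included in first bin
        assert spec.label_universe == MAF_BIN_LABELS

    def test_chromosome_scheme_counts_sum_to_m(self):
        snps = self._snps(30)
        spec = partition_snps(snps, "chromosome")
        assert sum(spec.counts().values()) == 30

    def test_region_window_closed_interval(self):
        snps = pd.DataFrame(
            {
                "snp": ["anchor", "left_in", "right_in", "left_out", "other_chrom"],
                "chrom": ["3", "3", "3", "3", "4"],
                "pos": [1_000_000, 750_000, 1_250_000, 749_999, 1_000_000],
                "a1": "A",
                "a2": "G",
            }
        )
        spec = partition_snps(snps, "snp_list_region", snp_list=["anchor"], window_kb=250)
        assert spec.labels["left_in"] == "region"
        assert spec.labels["right_in"] == "region"
        assert spec.labels["left_out"] == "background"
        assert spec.labels["other_chrom"] == "background"

    def test_missing_listed_snps_counted_not_fatal(self):
        snps = self._snps(10)
        spec = partition_snps(
            snps, "snp_list_region", snp_list=["s1", "rs_absent"], window_kb=1
        )
        assert spec.missing_inputs == ["rs_absent"]

    def test_genic_and_eqtl_schemes_follow_annotation(self):
        snps = self._snps(6)
        ann = pd.DataFrame(
            {
                "snp": [f"s{j}" for j in range(6)],
                "genic": [True, False, True, False, True, False],
                "eqtl_p": [0.001, 0.5, 0.009, 0.2, 0.05, 0.0001],
            }
        )
        genic = partition_snps(snps, "genic", annotation=ann)
        assert genic.counts() == {"genic": 3, "intergenic": 3}
        eqtl = partition_snps(snps, "eqtl_threshold", annotation=ann, eqtl_threshold=0.01)
        assert sorted(eqtl.snp_ids("eqtl")) == ["s0", "s2", "s5"]

    def test_schemes_are_mutually_exclusive_and_exhaustive(self):
        snps = self._snps(20)
        maf = np.linspace(0.02, 0.49, 20)
        spec = partition_snps(snps, "maf_bin", maf=maf)
        assert not spec.labels.index.duplicated().any()
        assert len(spec.labels) == 20

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            partition_snps(self._snps(), "bogus")


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(15)
        m = 800
        p1 = rng.uniform(0.2, 0.5, m)
        p2 = np.clip(p1 + rng.normal(0, 0.12, m), 0.05, 0.95)
        X = np.vstack(
            [rng.binomial(2, p1, size=(60, m)), rng.binomial(2, p2, size=(60, m))]
        ).astype(np.int8)
        grm = compute_grm(make_geno(X))
        res = pca(grm, 4)
        pop = np.r_[np.zeros(60), np.ones(60)]
        r = np.corrcoef(res.components[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_components_orthonormal(self):
        rng = np.random.default_rng(16)
        X = rng.binomial(2, 0.3, size=(40, 500)).astype(np.int8)
        res = pca(compute_grm(make_geno(X)), 5)
        gram = res.components.T @ res.components
        assert np.abs(gram - np.eye(5)).max() < 1e-8

    def test_identity_grm_flags_degenerate_spectrum(self):
        n = 30
        grm = GRMatrix(
            ids=[f"i{j}" for j in range(n)],
            A=np.eye(n),
            N=np.full((n, n), 10.0),
            n_snps=10,
        )
        res = pca(grm, 2)
        assert res.degenerate

    def test_k_must_be_below_n(self):
        grm = GRMatrix(ids=["a", "b"], A=np.eye(2), N=np.ones((2, 2)), n_snps=1)
        with pytest.raises(ValueError, match="k"):
            pca(grm, 2)
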
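"""Genotype QC: HWE and missingness tests, SNP and sample filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from gremlite.io import GRMatrix
from gremlite.qc import (
    STRINGENT_QC,
    QCConfig,
    differential_missingness_test,
    filter_samples,
    filter_snps,
    hwe_test,
)
from tests.conftest import make_geno


def hwe_exact_oracle(n_AA, n_Aa, n_aa):
    """Independent full enumeration over heterozygote counts at fixed
    allele counts (conditional distribution of Levene/Haldane)."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    probs = {}
    for het in range(min(nA, na) % 2, min(nA, na) + 1, 2):
        aa_ = (nA - het) // 2
        bb_ = (na - het) // 2
        logp = (
            het * np.log(2.0)
            + gammaln(n + 1) - gammaln(aa_ + 1) - gammaln(het + 1) - gammaln(bb_ + 1)
            + gammaln(nA + 1) + gammaln(na + 1) - gammaln(2 * n + 1)
        )
        probs[het] = np.exp(logp)
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_exact_hwe_proportions_give_p_one(self):
        # (25, 50, 25) are the p=q=0.5 Hardy-Weinberg proportions exactly
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_total_heterozygote_deficit_matches_enumeration(self):
        p = hwe_test(50, 0, 100, method="exact")
        assert p == pytest.approx(hwe_exact_oracle(50, 0, 100), rel=1e-9)
        assert p < 1e-30

    def test_monomorphic_is_p_one(self):
        assert hwe_test(0, 0, 30) == 1.0
        assert hwe_test(30, 0, 0) == 1.0

    def test_all_zero_counts_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert hwe_test(0, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 5, 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_AA=st.integers(0, 60), n_Aa=st.integers(0, 120), n_aa=st.integers(0, 60)
    )
    def test_exact_matches_enumeration_and_stays_in_unit_interval(self, n_AA, n_Aa, n_aa):
        if n_AA + n_Aa + n_aa == 0:
            return
        p = hwe_test(n_AA, n_Aa, n_aa, method="exact")
        assert 0.0 <= p <= 1.0
        nA = 2 * n_AA + n_Aa
        na = 2 * n_aa + n_Aa
        if nA and na:
            assert p == pytest.approx(hwe_exact_oracle(n_AA, n_Aa, n_aa), rel=1e-9)

    def test_chisq_agrees_with_exact_where_decisions_are_made(self):
        # The exact test's discreteness makes its p jump to 1 near the modal
        # heterozygote count, so global agreement with the 1-df chi-square is
        # impossible; what QC relies on is the tail.  Over 1,000 random HWE
        # tables with every expected class count >= 20: deep-tail p-values
        # (exact p <= 0.01) agree within 0.01, and the two variants never
        # disagree about rejection at the standard-regime 1e-4 threshold.
        rng = np.random.default_rng(0)
        pairs = []
        while len(pairs) < 2000:
            n = int(rng.integers(200, 600))
            p = rng.uniform(0.25, 0.75)
            counts = rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
            expected_min = n * min(p * p, 2 * p * (1 - p), (1 - p) * (1 - p))
            if expected_min < 20:
                continue
            pairs.append(
                (hwe_test(*counts, method="exact"), hwe_test(*counts, method="chisq"))
            )
        pairs = np.array(pairs)
        tail = pairs[pairs[:, 0] <= 0.01]
        assert len(tail) >= 10
        assert np.abs(tail[:, 0] - tail[:, 1]).max() <= 0.01
        assert np.all((pairs[:, 0] < 1e-4) == (pairs[:, 1] < 1e-4))


class TestDifferentialMissingness:
    def test_symmetric_table_p_one(self):
        assert differential_missingness_test(5, 95, 5, 95) == pytest.approx(1.0)

    def test_matches_fisher_hypergeometric_oracle(self):
        p = differential_missingness_test(10, 90, 0, 100)
        # enumeration over the hypergeometric: two-sided by probability mass
        expected = stats.fisher_exact([[10, 90], [0, 100]])[1]
        assert p == pytest.approx(expected, rel=1e-9)

    def test_zero_missing_anywhere_p_one(self):
        assert differential_missingness_test(0, 100, 0, 80) == 1.0


class TestFilterSnps:
    def _toy_panel(self):
        """6 SNPs: X-linked, rare, gappy, HWE-violating, two clean; n=150."""
        n = 150
        rng = np.random.default_rng(1)
        cols = {}
        clean = np.array([2] * 24 + [1] * 72 + [0] * 54, dtype=np.int8)  # exact HWE, p=0.4
        cols["x_linked"] = clean.copy()
        rare = np.zeros(n, dtype=np.int8)
        rare[0] = 1  # MAF 1/300 < 0.01
        cols["rare"] = rare
        gappy = clean.copy()
        gappy[:15] = -1  # 10% missing
        cols["gappy"] = gappy
        cols["hwe_bad"] = np.array([2] * 50 + [0] * 100, dtype=np.int8)  # (50, 0, 100)
        cols["clean1"] = clean.copy()
        cols["clean2"] = rng.permutation(clean)
        X = np.column_stack(list(cols.values()))
        chroms = ["X", "1", "1", "1", "1", "1"]
        return make_geno(X, chrom=chroms, snp_ids=list(cols)), n

    def test_stringent_regime_filter_order_and_counts(self):
        geno, n = self._toy_panel()
        status = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        cfg = QCConfig(**{**STRINGENT_QC.__dict__, "relatedness_max": None})
        out, report = filter_snps(geno, cfg, status=status)
        assert dict(report.steps) == {
            "non_autosomal": 1,
            "missingness": 1,
            "maf": 1,
            "hwe": 1,
            "differential_missingness": 0,
        }
        assert list(out.snps["snp"]) == ["clean1", "clean2"]
        assert report.n_surviving == 2

    def test_disabled_filters_are_identity(self):
        geno, _ = self._toy_panel()
        geno = geno.subset(snp_idx=geno.snps["chrom"].isin(["1"]).to_numpy())
        out, report = filter_snps(geno, QCConfig())
        assert out.m == geno.m
        assert all(c == 0 for _, c in report.steps)

    def test_filters_are_stateless(self):
        geno, n = self._toy_panel()
        status = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        cfg = QCConfig(**{**STRINGENT_QC.__dict__, "relatedness_max": None})
        _, r1 = filter_snps(geno, cfg, status=status)
        _, r2 = filter_snps(geno, cfg, status=status)
        assert r1.steps == r2.steps and r1.removed_ids == r2.removed_ids

    def test_rerun_on_filtered_output_is_noop(self):
        geno, n = self._toy_panel()
        status = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        cfg = QCConfig(**{**STRINGENT_QC.__dict__, "relatedness_max": None})
        once, _ = filter_snps(geno, cfg, status=status)
        twice, rep = filter_snps(once, cfg, status=status)
        assert twice.m == once.m and rep.n_removed == 0

    def test_differential_filter_needs_status(self):
        geno, _ = self._toy_panel()
        with pytest.raises(ValueError, match="no status"):
            filter_snps(geno, QCConfig(differential_missingness_p_min=0.05))

    def test_maf_boundary_is_strict(self):
        # MAF exactly at the threshold survives ("MAF < 0.01" removes)
        n = 200
        col = np.zeros(n, dtype=np.int8)
        col[:4] = 1  # MAF = 4/400 = 0.01
        geno = make_geno(col[:, None])
        out, _ = filter_snps(geno, QCConfig(maf_min=0.01))
        assert out.m == 1


class TestFilterSamples:
    def _geno(self, n=6, m=40, seed=0):
        rng = np.random.default_rng(seed)
        return make_geno(rng.binomial(2, 0.4, size=(n, m)).astype(np.int8))

    def _grm(self, geno, pairs):
        n = geno.n
        A = np.eye(n)
        for j, k, v in pairs:
            A[j, k] = A[k, j] = v
        return GRMatrix(ids=geno.sample_ids.tolist(), A=A, N=np.full((n, n), 40.0), n_snps=40)

    def test_clean_samples_untouched(self):
        geno = self._geno()
        grm = self._grm(geno, [(0, 1, 0.02)])
        out, report = filter_samples(
            geno, QCConfig(sample_call_rate_min=0.5, relatedness_max=0.05), grm
        )
        assert out.n == geno.n and report.n_removed == 0

    def test_tied_call_rates_drop_later_sample(self):
        geno = self._geno()
        grm = self._grm(geno, [(1, 3, 0.9)])
        out, report = filter_samples(geno, QCConfig(relatedness_max=0.05), grm)
        assert report.removed_ids["relatedness"] == [geno.sample_ids[3]]
        assert out.n == geno.n - 1

    def test_related_chain_pruned_greedily(self):
        # A-B and B-C above threshold, A-C below: dropping B suffices
        geno = self._geno()
        grm = self._grm(geno, [(0, 1, 0.7), (1, 2, 0.6), (0, 2, 0.01)])
        out, report = filter_samples(geno, QCConfig(relatedness_max=0.05), grm)
        assert report.removed_ids["relatedness"] == [geno.sample_ids[1]]
        assert out.n == geno.n - 1

    def test_lower_call_rate_member_dropped_first(self):
        geno = self._geno(seed=3)
        geno.X[0, :10] = -1  # sample 0 has the lower call rate
        grm = self._grm(geno, [(0, 1, 0.5)])
        _, report = filter_samples(geno, QCConfig(relatedness_max=0.05), grm)
        assert report.removed_ids["relatedness"] == [geno.sample_ids[0]]

    def test_relatedness_without_grm_is_config_error(self):
        with pytest.raises(ValueError, match="no GRM"):
            filter_samples(self._geno(), QCConfig(relatedness_max=0.05))
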
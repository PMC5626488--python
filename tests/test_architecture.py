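"""Partitioned heritability analyses and region/conditioning operations."""

import numpy as np
import pandas as pd
import pytest

from gremlite.architecture import (
    chromosome_lengths,
    h2_length_regression,
    maf_bin_h2,
    per_chromosome_h2,
    rare_variant_model_h2,
    region_exclude_or_condition,
)
from gremlite.grm import compute_grm
from gremlite.reml import fit_reml
from gremlite.sim import SimConfig, simulate_genotypes, simulate_liability_phenotype


@pytest.fixture(scope="module")
def chr1_loaded_cohort():
    """All causal variance on chromosome 1 of a 4-chromosome panel."""
    cfg = SimConfig(
        n_samples=500, n_snps=800, maf_spec=(0.1, 0.5),
        per_partition_h2={"all": 0.5}, causal_fraction=0.5,
        n_chromosomes=4, seed=61,
    )
    geno = simulate_genotypes(cfg)
    chr1 = np.flatnonzero((geno.snps["chrom"] == "1").to_numpy())
    _, truth = simulate_liability_phenotype(geno, cfg, partition={"all": chr1})
    return geno, truth.liability


class TestPerChromosome:
    def test_planted_chromosome_dominates(self, chr1_loaded_cohort):
        geno, y = chr1_loaded_cohort
        part = per_chromosome_h2(geno, y, None)
        table = part.table.set_index("label")
        assert table.loc["1", "h2_obs"] == table["h2_obs"].max()
        assert part.joint

    def test_joint_sum_close_to_single_grm(self, chr1_loaded_cohort):
        geno, y = chr1_loaded_cohort
        part = per_chromosome_h2(geno, y, None)
        single = fit_reml(y, None, [compute_grm(geno)])
        gap = abs(part.table["h2_obs"].sum() - single.h2_obs[0])
        assert gap < max(part.table["h2_obs_se"].sum(), 0.05)

    def test_single_chromosome_rejected(self):
        cfg = SimConfig(n_samples=60, n_snps=100, n_chromosomes=1, seed=62, maf_spec=(0.2, 0.5))
        geno = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match=">= 2 chromosomes"):
            per_chromosome_h2(geno, np.random.default_rng(0).standard_normal(60), None)

    def test_duplicated_chromosomes_unidentifiable(self):
        from gremlite.reml import IdentifiabilityError

        cfg = SimConfig(n_samples=100, n_snps=60, n_chromosomes=1, seed=63, maf_spec=(0.2, 0.5))
        geno = simulate_genotypes(cfg)
        # duplicate the panel under a second chromosome label
        dup = geno.snps.copy()
        dup["chrom"] = "2"
        dup["snp"] = dup["snp"] + "_b"
        geno.snps = pd.concat([geno.snps, dup], ignore_index=True)
        geno.X = np.hstack([geno.X, geno.X])
        y = np.random.default_rng(1).standard_normal(100)
        with pytest.raises(IdentifiabilityError):
            per_chromosome_h2(geno, y, None)


class TestLengthRegression:
    def test_perfect_linear_relation(self):
        table = pd.DataFrame(
            {"label": [str(c) for c in range(1, 8)], "h2_obs": np.arange(1, 8) * 0.01}
        )
        lengths = pd.Series(
            np.arange(1, 8) * 1e7, index=[str(c) for c in range(1, 8)]
        )
        reg = h2_length_regression(table, lengths)
        assert reg.r == pytest.approx(1.0)
        assert reg.outliers == []

    def test_outlier_chromosome_flagged(self):
        h2 = np.arange(1, 11) * 0.01
        h2[4] += 0.25  # one chromosome far above the trend
        table = pd.DataFrame({"label": [str(c) for c in range(1, 11)], "h2_obs": h2})
        lengths = pd.Series(np.arange(1, 11) * 1e7, index=[str(c) for c in range(1, 11)])
        reg = h2_length_regression(table, lengths)
        assert "5" in reg.outliers

    def test_zero_length_variance_rejected(self):
        table = pd.DataFrame({"label": ["1", "2", "3"], "h2_obs": [0.1, 0.2, 0.3]})
        lengths = pd.Series([5.0, 5.0, 5.0], index=["1", "2", "3"])
        with pytest.raises(ValueError, match="zero variance"):
            h2_length_regression(table, lengths)

    def test_needs_three_points(self):
        table = pd.DataFrame({"label": ["1", "2"], "h2_obs": [0.1, 0.2]})
        lengths = pd.Series([1.0, 2.0], index=["1", "2"])
        with pytest.raises(ValueError, match="at least 3"):
            h2_length_regression(table, lengths)

    def test_chromosome_lengths_are_position_spans(self, chr1_loaded_cohort):
        geno, _ = chr1_loaded_cohort
        lengths = chromosome_lengths(geno)
        sub = geno.snps[geno.snps["chrom"] == "1"]
        assert lengths["1"] == float(sub["pos"].max() - sub["pos"].min())


class TestMafBins:
    def test_bin_counts_partition_panel(self):
        cfg = SimConfig(n_samples=300, n_snps=600, maf_spec=(0.05, 0.5),
                        per_partition_h2={"all": 0.4}, seed=64)
        geno = simulate_genotypes(cfg)
        _, truth = simulate_liability_phenotype(geno, cfg)
        part = maf_bin_h2(geno, truth.liability, None)
        assert part.table["n_snps"].sum() == geno.m

    def test_empty_bins_dropped_with_warning(self):
        cfg = SimConfig(n_samples=400, n_snps=300, maf_spec=(0.35, 0.5),
                        per_partition_h2={"all": 0.4}, seed=69)
        geno = simulate_genotypes(cfg)
        _, truth = simulate_liability_phenotype(geno, cfg)
        with pytest.warns(UserWarning, match="empty partition"):
            part = maf_bin_h2(geno, truth.liability, None)
        assert part.table["n_snps"].sum() == geno.m
        assert len(part.table) < 6

    def test_low_frequency_causal_bin_carries_signal(self):
        rng = np.random.default_rng(65)
        m = 1000
        mafs = np.where(np.arange(m) < 300, rng.uniform(0.02, 0.05, m), rng.uniform(0.2, 0.5, m))
        cfg = SimConfig(n_samples=600, n_snps=m, maf_spec=mafs,
                        per_partition_h2={"all": 0.5}, causal_fraction=0.8, seed=65)
        geno = simulate_genotypes(cfg)
        low_bin = np.flatnonzero(geno.maf() <= 0.05)
        _, truth = simulate_liability_phenotype(geno, cfg, partition={"all": low_bin})
        part = maf_bin_h2(geno, truth.liability, None)
        table = part.table.set_index("label")
        assert table.loc["(0.01,0.05]", "h2_obs"] == table["h2_obs"].max()


class TestRareVariantModel:
    def test_full_panel_ceiling_is_identity_regime(self):
        cfg = SimConfig(n_samples=250, n_snps=400, maf_spec=(0.1, 0.5),
                        per_partition_h2={"all": 0.4}, seed=66)
        geno = simulate_genotypes(cfg)
        _, truth = simulate_liability_phenotype(geno, cfg)
        with pytest.warns(UserWarning, match="clamped"):
            rv = rare_variant_model_h2(geno, truth.liability, None, maf_ceiling=0.5)
        assert rv.beta == pytest.approx(1.0)
        assert rv.c == 0.0
        un = fit_reml(truth.liability, None, [compute_grm(geno)])
        assert rv.fit.h2_obs[0] == pytest.approx(un.h2_obs[0], abs=1e-9)

    def test_ceiling_is_required_and_validated(self):
        cfg = SimConfig(n_samples=50, n_snps=60, seed=67, maf_spec=(0.2, 0.5))
        geno = simulate_genotypes(cfg)
        y = np.random.default_rng(2).standard_normal(50)
        with pytest.raises(ValueError, match="maf_ceiling"):
            rare_variant_model_h2(geno, y, None, maf_ceiling=0.0)
        with pytest.raises(ValueError, match="no SNPs"):
            rare_variant_model_h2(geno, y, None, maf_ceiling=0.001)

    def test_calibration_brings_estimate_closer_under_imperfect_tagging(self):
        # causal low-MAF variants are dropped from the panel and only tagged
        # through LD partners: the adjusted estimate should beat the raw
        # subset-GRM estimate in most replicates
        wins = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            m = 1200
            mafs = np.where(
                np.arange(m) % 4 < 2, rng.uniform(0.02, 0.1, m), rng.uniform(0.1, 0.5, m)
            )
            cfg = SimConfig(n_samples=400, n_snps=m, maf_spec=mafs, ld_block_size=4,
                            ld_r=0.7, per_partition_h2={"all": 0.4},
                            causal_fraction=0.5, seed=seed)
            geno = simulate_genotypes(cfg)
            low = np.flatnonzero(geno.maf() <= 0.1)
            _, truth = simulate_liability_phenotype(geno, cfg, partition={"all": low[::2]})
            causal_ids = set(truth.causal_snps["all"][::2])
            panel = geno.subset(snp_idx=~geno.snps["snp"].isin(causal_ids).to_numpy())
            rv = rare_variant_model_h2(panel, truth.liability, None, maf_ceiling=0.1)
            raw = fit_reml(
                truth.liability, None,
                [compute_grm(panel, snp_subset=np.flatnonzero(panel.maf() <= 0.1))],
            )
            wins += abs(rv.fit.h2_obs[0] - 0.4) <= abs(raw.h2_obs[0] - 0.4)
        assert wins >= 14


@pytest.fixture(scope="module")
def single_locus_cohort():
    cfg = SimConfig(n_samples=500, n_snps=400, maf_spec=(0.2, 0.5),
                    per_partition_h2={"all": 0.4}, causal_fraction=1.0,
                    n_chromosomes=2, seed=68)
    geno = simulate_genotypes(cfg)
    _, truth = simulate_liability_phenotype(geno, cfg, partition={"all": np.array([7])})
    return geno, truth


class TestRegionOps:

    def test_excluding_empty_region_is_bit_identical(self, single_locus_cohort):
        geno, truth = single_locus_cohort
        base = fit_reml(truth.liability, None, [compute_grm(geno)])
        excl = region_exclude_or_condition(
            geno, truth.liability, None, region=("9", 1, 10_000), mode="exclude"
        )
        assert excl.variances.tolist() == base.variances.tolist()
        assert excl.logL == base.logL

    def test_conditioning_on_causal_snp_collapses_h2(self, single_locus_cohort):
        geno, truth = single_locus_cohort
        causal = truth.causal_snps["all"][0]
        base = fit_reml(truth.liability, None, [compute_grm(geno)])
        cond = region_exclude_or_condition(
            geno, truth.liability, None, snp_id=causal, mode="condition"
        )
        assert cond.h2_obs[0] < 0.25 * base.h2_obs[0]

    def test_exclude_and_condition_commute_when_disjoint(self, single_locus_cohort):
        geno, truth = single_locus_cohort
        causal = truth.causal_snps["all"][0]
        assert geno.snps.loc[geno.snp_index(causal), "chrom"] == "1"
        region = ("2", 1, 50_000)
        inside = (
            (geno.snps["chrom"] == "2")
            & (geno.snps["pos"] >= 1)
            & (geno.snps["pos"] <= 50_000)
        ).to_numpy()
        pruned = geno.subset(snp_idx=~inside)
        a = region_exclude_or_condition(
            pruned, truth.liability, None, snp_id=causal, mode="condition"
        )
        dose = geno.X[:, geno.snp_index(causal)].astype(float)
        b = region_exclude_or_condition(
            geno, truth.liability, dose[:, None], region=region, mode="exclude"
        )
        assert a.h2_obs[0] == pytest.approx(b.h2_obs[0], abs=1e-8)

    def test_unknown_snp_rejected(self, single_locus_cohort):
        geno, truth = single_locus_cohort
        with pytest.raises(KeyError):
            region_exclude_or_condition(
                geno, truth.liability, None, snp_id="rs_missing", mode="condition"
            )
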
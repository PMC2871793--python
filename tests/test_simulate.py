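"""Tests for the synthetic-data generators: determinism, configured
structure, and calibration of the null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from castebias.errors import ConfigurationError
from castebias.qpcr import analysis_matrices
from castebias.simulate import (
    ExpressionSimConfig,
    GenotypeSimConfig,
    SpectralSimConfig,
    simulate_expression_study,
    simulate_genotype_table,
    simulate_spectral_study,
)
from castebias.stats import _rank_sum_counts, exact_null_p_table, mann_whitney_u


class TestSeedDeterminism:
    def test_expression_repeat_identical(self):
        a = simulate_expression_study(ExpressionSimConfig(seed=3))
        b = simulate_expression_study(ExpressionSimConfig(seed=3))
        pd.testing.assert_frame_equal(a.quantities, b.quantities)
        c = simulate_expression_study(ExpressionSimConfig(seed=4))
        assert not a.quantities.equals(c.quantities)

    def test_spectral_repeat_identical(self):
        a = simulate_spectral_study(SpectralSimConfig(seed=5))
        b = simulate_spectral_study(SpectralSimConfig(seed=5))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.spike_in, b.spike_in)

    def test_genotype_repeat_identical(self):
        a = simulate_genotype_table(GenotypeSimConfig(seed=6))
        b = simulate_genotype_table(GenotypeSimConfig(seed=6))
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)


class TestConfigValidation:
    def test_bad_expression_configs(self):
        with pytest.raises(ConfigurationError, match="group sizes"):
            ExpressionSimConfig(n_group1=1).validate()
        with pytest.raises(ConfigurationError, match=r"\[0, 1\)"):
            ExpressionSimConfig(
                correlation_blocks=[(("g01", "g02"), 1.0)]
            ).validate()
        with pytest.raises(ConfigurationError, match="control gene"):
            ExpressionSimConfig(
                correlation_blocks=[(("RSP8", "g02"), 0.5)]
            ).validate()
        with pytest.raises(ConfigurationError, match="missing_rate"):
            ExpressionSimConfig(missing_rate=1.2).validate()

    def test_bad_spectral_configs(self):
        with pytest.raises(ConfigurationError, match="spike_in_mean"):
            SpectralSimConfig(spike_in_mean=0.0).validate()
        with pytest.raises(ConfigurationError, match="decoy"):
            SpectralSimConfig(de_hit_ids=["decoy01", "hit01"]).validate()

    def test_bad_genotype_configs(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            GenotypeSimConfig(n_loci=1, allele_freqs=[[0.5, 0.2]]).validate()
        with pytest.raises(ConfigurationError, match="<= 1"):
            GenotypeSimConfig(male_fraction=0.8, triploid_fraction=0.4).validate()


class TestExpressionStructure:
    def test_missing_cells_are_nan_never_zero(self):
        study = simulate_expression_study(
            ExpressionSimConfig(seed=8, missing_rate=0.2)
        )
        vals = study.quantities.to_numpy()
        assert np.isnan(vals).any()
        assert np.nanmin(vals) > 0
        # control gene never missing
        assert not study.quantities.loc[study.control_gene_id].isna().any()
        assert len(study.truth["missing_cells"]) == int(
            np.isnan(vals[:-1].reshape(38, 17, 3)[:, :, 0]).sum()
        )

    def test_block_correlation_converges_to_target(self):
        """Realized pairwise Pearson r inside a block approaches the
        configured value at large sample size (|diff| < 0.05 at n=10^4)."""
        cfg = ExpressionSimConfig(
            n_group1=5000,
            n_group2=5000,
            n_genes=4,
            de_gene_ids=[],
            correlation_blocks=[(("g01", "g02", "g03"), 0.93)],
            triplicate_cv=0.0,
            missing_rate=0.0,
            n_replicates=1,
            seed=9,
        )
        study = simulate_expression_study(cfg)
        log2 = np.log2(study.quantities.xs(1, axis=1, level="rep"))
        norm = log2 - log2.loc["RSP8"]
        for a, b in [("g01", "g02"), ("g01", "g03"), ("g02", "g03")]:
            r = np.corrcoef(norm.loc[a], norm.loc[b])[0, 1]
            assert abs(r - 0.93) < 0.05
        # genes outside the block stay uncorrelated
        r_out = np.corrcoef(norm.loc["g01"], norm.loc["g04"])[0, 1]
        assert abs(r_out) < 0.05

    def test_de_genes_shifted_in_group2_only(self):
        cfg = ExpressionSimConfig(seed=10, log2_effect=4.0, missing_rate=0.0)
        study = simulate_expression_study(cfg)
        imputed, _, _ = analysis_matrices(study)
        wr = study.groups[study.groups == "WR"].index
        fr = study.groups[study.groups == "FR"].index
        delta = imputed[wr].mean(axis=1) - imputed[fr].mean(axis=1)
        assert (delta.loc[cfg.de_gene_ids] > 2.0).all()
        null_genes = [g for g in imputed.index if g not in set(cfg.de_gene_ids)]
        assert delta.loc[null_genes].abs().mean() < 1.0

    def test_null_pvalues_uniform_after_randomized_pit(self):
        """Raw exact Mann-Whitney p-values from null-configured studies
        follow their (discrete, conservative) permutation null; after a
        randomized probability integral transform they are exactly
        U(0,1), which a KS test at alpha=0.01 should not reject."""
        rng = np.random.default_rng(12)
        pvals = []
        for s in range(25):
            cfg = ExpressionSimConfig(
                seed=1000 + s, de_gene_ids=[], correlation_blocks=[]
            )
            study = simulate_expression_study(cfg)
            imputed, _, _ = analysis_matrices(study)
            fr = study.groups[study.groups == "FR"].index
            wr = study.groups[study.groups == "WR"].index
            for g in imputed.index:
                _, p = mann_whitney_u(
                    imputed.loc[g, fr], imputed.loc[g, wr], mode="exact"
                )
                pvals.append(p)
        # exact null CDF of the two-sided p for untied (10, 7) data
        doubled = tuple(range(2, 2 * 17 + 1, 2))
        counts = _rank_sum_counts(doubled, 10)
        table = exact_null_p_table(np.arange(1.0, 18.0), 10)
        support = np.nonzero(counts)[0]
        p_of_u = table[support - 10 * 11]
        pmf = counts[support] / counts.sum()
        atoms = {}
        for pv, pr in zip(p_of_u, pmf):
            atoms[round(pv, 12)] = atoms.get(round(pv, 12), 0.0) + pr
        levels = np.array(sorted(atoms))
        mass = np.array([atoms[v] for v in levels])
        cdf = np.cumsum(mass)
        idx = np.searchsorted(levels, np.round(pvals, 12))
        upper = cdf[idx]
        lower = upper - mass[idx]
        u = lower + rng.random(len(pvals)) * (upper - lower)
        assert sps.kstest(u, "uniform").pvalue > 0.01

    def test_rejection_rate_matches_exact_attainable_level(self):
        """P(exact p <= 0.05) under the null equals the largest attainable
        level below 0.05 (0.0431 for 10 vs 7) — the discrete test is
        conservative at the nominal level, and simulation agrees within
        binomial error."""
        hits = total = 0
        for s in range(25):
            cfg = ExpressionSimConfig(
                seed=2000 + s, de_gene_ids=[], correlation_blocks=[]
            )
            study = simulate_expression_study(cfg)
            imputed, _, _ = analysis_matrices(study)
            fr = study.groups[study.groups == "FR"].index
            wr = study.groups[study.groups == "WR"].index
            for g in imputed.index:
                _, p = mann_whitney_u(imputed.loc[g, fr], imputed.loc[g, wr])
                hits += p <= 0.05
                total += 1
        level = 0.043089  # attainable level just below 0.05 at (10, 7)
        se = np.sqrt(level * (1 - level) / total)
        assert abs(hits / total - level) < 4 * se


class TestSpectralStructure:
    def test_counts_nonnegative_integers(self):
        t = simulate_spectral_study(SpectralSimConfig(seed=13))
        vals = t.counts.to_numpy()
        assert np.issubdtype(vals.dtype, np.integer)
        assert (vals >= 0).all()
        assert (t.spike_in >= 0).all()

    def test_no_fold_change_means_balanced_groups(self):
        cfg = SpectralSimConfig(
            seed=14, de_hit_ids=[], fold_change={}, n_hits=30,
            base_intensity=20.0, lane_loading=[1.0] * 10,
        )
        t = simulate_spectral_study(cfg)
        totals = t.sample_totals()
        fr = totals[t.groups[t.groups == "FR"].index].to_numpy().mean()
        wr = totals[t.groups[t.groups == "WR"].index].to_numpy().mean()
        assert abs(fr - wr) / fr < 0.05

    def test_doubled_lane_loading_doubles_expected_totals(self):
        """A sample with lane factor 2 has twice the expected raw total;
        with 3000 hit draws the relative Poisson error is ~1.3%."""
        cfg = SpectralSimConfig(
            seed=15, n_hits=3000, de_hit_ids=[], fold_change={},
            base_intensity=10.0, decoy_fraction=0.0,
            lane_loading=[1.0, 1.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        )
        t = simulate_spectral_study(cfg)
        totals = t.sample_totals().sum(axis=0)
        expected = 2 * 10.0 * 3000
        se = np.sqrt(expected)
        assert abs(totals.iloc[2] - expected) < 3 * se

    def test_in_liquid_has_single_band_no_spike(self):
        t = simulate_spectral_study(SpectralSimConfig(seed=16, mode="in_liquid"))
        assert t.spike_in is None
        assert list(t.counts.columns.get_level_values("band").unique()) == [1]


class TestGenotypeStructure:
    def test_truth_allocation_is_deterministic(self):
        t = simulate_genotype_table(GenotypeSimConfig(seed=17))
        counts = t.truth.value_counts()
        assert counts["male"] == 18  # round(18/29 * 29)
        assert counts["triploid"] == 1
        assert counts["female"] == 10

    def test_haploids_show_one_allele_per_amplified_locus(self):
        t = simulate_genotype_table(
            GenotypeSimConfig(seed=18, amplification_failure_rate=0.2)
        )
        for sp in t.truth[t.truth == "male"].index:
            for alleles in t.genotypes.loc[sp]:
                assert len(alleles) in (0, 1)

    def test_no_triploids_configured_means_no_triple_calls(self):
        t = simulate_genotype_table(
            GenotypeSimConfig(seed=19, triploid_fraction=0.0, n_specimens=200)
        )
        assert all(
            len(a) <= 2 for row in t.genotypes.itertuples(index=False) for a in row
        )

    def test_failed_loci_marked_empty(self):
        t = simulate_genotype_table(
            GenotypeSimConfig(seed=20, amplification_failure_rate=0.5, n_specimens=50)
        )
        assert any(
            len(a) == 0 for row in t.genotypes.itertuples(index=False) for a in row
        )
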
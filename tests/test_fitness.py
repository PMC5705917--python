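"""Unit tests for trimming, RpK, the Gaussian histogram fit and calling."""

import math

import numpy as np
import pandas as pd
import pytest

import tnscreen as tn
from tnscreen.errors import (
    ConfigError,
    DegenerateDistributionError,
    ValidationError,
)
from tnscreen.fitness import Call, FitnessCall


def make_sites(length, sites):
    return tn.InsertionSiteCounts("gA", length, tuple(sites))


class TestTrimming:
    @pytest.mark.parametrize(
        "length,sites,expected",
        [
            # first-5% and last-10% sites dropped, central kept
            (1000, [(10, 5), (500, 7), (950, 9)], [(500, 7)]),
            # site exactly at 5% of length is discarded, exactly at 90% kept
            (1000, [(50, 1), (900, 2)], [(900, 2)]),
            (100, [(3, 50)], []),
        ],
    )
    def test_positional_rule(self, length, sites, expected):
        trimmed = tn.trim_gene_sites(make_sites(length, sites))
        assert list(trimmed.sites) == expected

    def test_zero_fractions_are_identity(self):
        s = make_sites(1000, [(1, 3), (500, 7), (1000, 2)])
        assert tn.trim_gene_sites(s, 0.0, 0.0).sites == s.sites

    def test_counts_and_order_preserved(self):
        s = make_sites(1000, [(200, 5), (400, 1), (600, 9)])
        assert tn.trim_gene_sites(s).sites == s.sites

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            tn.trim_gene_sites(make_sites(100, [(50, 1)]), 0.6, 0.5)

    def test_position_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            make_sites(100, [(101, 1)])


class TestRpk:
    def test_direct_formula(self):
        v = tn.gene_rpk(make_sites(500, [(250, 100)]))
        assert v.rpk == pytest.approx(200.0)

    def test_log2_value(self):
        v = tn.gene_rpk(make_sites(1000, [(500, 1000)]))
        assert v.rpk == pytest.approx(1000.0)
        assert v.log2_rpk == pytest.approx(math.log2(1000), abs=1e-9)

    def test_zero_total_gets_pseudocount(self):
        v = tn.gene_rpk(make_sites(1000, []))
        assert v.rpk == 0.0
        assert v.zero_adjusted
        assert v.log2_rpk == pytest.approx(math.log2(0.5 / 1.0))


class TestNormalFit:
    def test_recovers_sample_moments(self):
        rng = np.random.default_rng(42)
        v = rng.normal(8.0, 1.2, 5000)
        fit = tn.fit_normal_to_histogram(v, 0.25)
        assert abs(fit.mu - 8.0) < 0.1
        assert abs(fit.sigma - 1.2) < 0.1
        # tighter: against the same draw's own moments
        assert abs(fit.mu - v.mean()) < 0.05 * fit.sigma
        assert abs(fit.sigma - v.std(ddof=1)) < 0.05 * fit.sigma

    def test_symmetric_grid_centres_exactly(self):
        # Gaussian-proportional multiplicities on an exact grid around 5.0
        offsets = np.arange(-12, 13) * 0.25
        mult = np.rint(1000 * np.exp(-(offsets**2) / (2 * 1.0**2))).astype(int)
        values = np.repeat(5.0 + offsets, mult)
        fit = tn.fit_normal_to_histogram(values, 0.25)
        assert fit.mu == pytest.approx(5.0, abs=1e-6)

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            tn.fit_normal_to_histogram([3.0] * 40, 0.25)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            tn.fit_normal_to_histogram(np.arange(10.0), 0.25)


class TestClassification:
    def test_critical_value(self):
        assert tn.critical_z(0.05) == pytest.approx(1.959964, abs=1e-6)

    @pytest.mark.parametrize(
        "z,expected",
        [
            (-3.0, Call.REDUCED),
            (0.0, Call.NEUTRAL),
            (1.959963, Call.NEUTRAL),  # just inside the band
            (1.97, Call.INCREASED),
            (-1.97, Call.REDUCED),
        ],
    )
    def test_band_boundaries(self, z, expected):
        fit = tn.NormalFitResult(
            mu=8.0, sigma=1.0, amplitude=100.0, rmse=0.0, n_bins=30,
            bin_width=0.25,
        )
        got_z, call = tn.classify_value(8.0 + z, fit, alpha=0.05)
        assert got_z == pytest.approx(z)
        assert call is expected


class TestConsensus:
    def fc(self, call, rep=1, gene="gA", tp=3.0):
        return FitnessCall(gene, tp, rep, 0.0, call)

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            (Call.REDUCED, Call.REDUCED, Call.REDUCED),
            (Call.INCREASED, Call.INCREASED, Call.INCREASED),
            (Call.REDUCED, Call.NEUTRAL, Call.NEUTRAL),
            (Call.REDUCED, Call.INCREASED, Call.NEUTRAL),
            (Call.NEUTRAL, Call.NEUTRAL, Call.NEUTRAL),
        ],
    )
    def test_both_replicates_required(self, c1, c2, expected):
        assert tn.consensus_call(self.fc(c1, 1), self.fc(c2, 2)) is expected

    def test_mismatched_gene_rejected(self):
        with pytest.raises(ValidationError):
            tn.consensus_call(self.fc(Call.REDUCED), self.fc(Call.REDUCED, gene="gB"))

    def test_mismatched_timepoint_rejected(self):
        with pytest.raises(ValidationError):
            tn.consensus_call(
                self.fc(Call.REDUCED, tp=3.0), self.fc(Call.REDUCED, tp=7.0)
            )


class TestEarliest:
    def test_earliest_nonneutral_wins(self):
        calls = [(3.0, Call.NEUTRAL), (7.0, Call.REDUCED), (14.0, Call.REDUCED)]
        assert tn.earliest_nonneutral(calls) == (Call.REDUCED, 7.0)

    def test_all_neutral_is_none(self):
        assert tn.earliest_nonneutral([(3.0, Call.NEUTRAL)]) is None

    def test_increased_first_wins_regardless_of_later(self):
        calls = [(3.0, Call.INCREASED), (7.0, Call.REDUCED)]
        assert tn.earliest_nonneutral(calls) == (Call.INCREASED, 3.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            tn.earliest_nonneutral([])

    def test_unordered_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            tn.earliest_nonneutral([(7.0, Call.NEUTRAL), (3.0, Call.NEUTRAL)])


class TestLongevitySet:
    def earliest(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "earliest_call", "earliest_timepoint"]
        )

    def test_reduced_in_window_is_in_set(self):
        df = tn.build_longevity_set(self.earliest([("gA", "reduced", 7.0)]))
        assert df.loc[0, "in_longevity_set"]

    def test_day30_only_is_excluded_from_window(self):
        df = tn.build_longevity_set(self.earliest([("gA", "reduced", 30.0)]))
        assert not df.loc[0, "in_longevity_set"]

    def test_exclusion_list_removes_gene(self):
        df = tn.build_longevity_set(
            self.earliest([("gA", "reduced", 3.0)]), exclusion_lists=[["gA"]]
        )
        assert not df.loc[0, "in_longevity_set"]

    def test_increased_or_neutral_not_in_set(self):
        df = tn.build_longevity_set(
            self.earliest(
                [("gA", "increased", 3.0), ("gB", pd.NA, np.nan)]
            )
        )
        assert not df["in_longevity_set"].any()


class TestPipeline:
    def test_requires_two_replicates(self, small_pool, small_screen):
        counts, manifest = small_screen
        with pytest.raises(ValidationError):
            tn.run_fitness_pipeline(
                counts, manifest[manifest.replicate == 1], small_pool.genes
            )

    def test_unknown_sample_rejected(self, small_pool, small_screen):
        counts, manifest = small_screen
        bad = counts.copy()
        bad.loc[bad.index[:5], "sample_id"] = "mystery"
        with pytest.raises(ValidationError):
            tn.run_fitness_pipeline(bad, manifest, small_pool.genes)

    def test_fit_population_is_all_genes_in_sample(self, small_results, small_pool):
        # exclusions act on the final set only; per-sample tables cover
        # every gene present in that sample's counts
        table = small_results.sample_tables["t0d_r1"]
        assert len(table) == len(small_pool.genes)

    def test_scale_equivariance_of_calls(self, small_pool, small_screen):
        """Multiplying every count by a constant shifts mu but not calls."""
        counts, manifest = small_screen
        base = tn.run_fitness_pipeline(counts, manifest, small_pool.genes)
        scaled = counts.assign(count=counts["count"] * 8)
        res = tn.run_fitness_pipeline(scaled, manifest, small_pool.genes)
        for s in base.sample_tables:
            assert res.fits[s].mu == pytest.approx(
                base.fits[s].mu + 3.0, abs=0.05
            )
            pd.testing.assert_series_equal(
                res.sample_tables[s]["call"], base.sample_tables[s]["call"]
            )

    def test_exclusions_trim_final_set_only(self, small_pool, small_screen):
        counts, manifest = small_screen
        base = tn.run_fitness_pipeline(counts, manifest, small_pool.genes)
        victims = base.longevity_genes[:2]
        res = tn.run_fitness_pipeline(
            counts, manifest, small_pool.genes, exclusion_lists=[victims]
        )
        assert set(res.longevity_genes) == set(base.longevity_genes) - set(victims)
        assert res.fits.keys() == base.fits.keys()
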
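"""Cohort summaries: category matrix reconciliation, headline numbers,
histograms, ECDF, population bias, the t-test and feature statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aacds.classifier import classify_cohort
from aacds.fixtures import generate, random_plan
from aacds.store import AnnotationStore
from aacds.summaries import (
    category_matrix,
    feature_type_distribution,
    headline_stats,
    maf_distribution_by_category,
    maf_group_summary,
    population_bias_groups,
    prediction_count_histogram,
    relative_feature_position,
    round_half_away,
    score_ecdf,
    two_sample_ttest,
    verify_reconciliation,
)
from aacds.types import SequenceFeatureRecord

# Per-genome known-variant counts from the packaged 12-genome cohort
# (4 African then 8 Caucasian subjects).
AFRICAN_COUNTS = [88, 71, 77, 58]
CAUCASIAN_COUNTS = [57, 52, 50, 55, 60, 82, 72, 75]


class TestCategoryMatrix:
    def test_grand_unique_total(self, table2_results):
        matrix = category_matrix(table2_results)
        assert matrix.loc["unique", "total"] == 797
        assert list(matrix.loc["unique"][:-1]) == AFRICAN_COUNTS + CAUCASIAN_COUNTS

    def test_reconciliation_identity(self, table2_results):
        assert verify_reconciliation(table2_results)

    def test_empty_results(self):
        matrix = category_matrix([])
        assert list(matrix.columns) == ["total"]
        assert (matrix["total"] == 0).all()


class TestHeadline:
    def test_printed_cohort_numbers(self, table2_results):
        """Mean 3.33 top-priority variants/genome; 35 deleterious
        associated variants, 7x the 5 documented causal instances; 15%
        of the 229 associated labels; 170 neutral associated; a
        98-variant priority evaluation space."""
        stats = headline_stats(table2_results)
        assert round(stats.mean_top_priority_per_genome, 2) == 3.33
        assert stats.combined_2b_3b == 35
        assert stats.ratio_2b3b_to_cat1 == 7.0
        assert round_half_away(stats.share_2b3b_of_2a3a_percent) == 15
        assert stats.label_totals["5"] == 170
        assert stats.priority_space_label_sum == 98

    def test_label_sum_vs_deduplicated(self, table2_results):
        """The label-sum convention counts a variant once per severe
        label; deduplication collapses 2B∩3B overlaps and category-1
        marks carried by already-counted deleterious variants."""
        stats = headline_stats(table2_results)
        assert stats.top_priority_label_sum == 40  # 5 + 14 + 21
        assert stats.top_priority_unique == 30  # |2B ∪ 3B| ⊇ all cat-1 here
        assert stats.priority_space_unique == 88  # 30 + 58 category-4


class TestHistogram:
    def test_packaged_cohort_consensus_mass(self, table2_results):
        """88 of the 797 known variants (11%) reach the 3-program
        consensus, mirroring the reported fraction."""
        consensus, conservation = prediction_count_histogram(
            (r.features.consensus_count for r in table2_results),
            (r.conservation_count for r in table2_results),
        )
        assert consensus.sum() == 797 == conservation.sum()
        assert consensus[consensus.index >= 3].sum() == 88

    def test_all_empty_profiles(self):
        consensus, conservation = prediction_count_histogram([0, 0, 0], [0, 0, 0])
        assert consensus[0] == 3 and conservation[0] == 3
        assert consensus[1:].sum() == 0


class TestEcdf:
    def test_single_score(self):
        curve = score_ecdf([0.5])
        assert curve.values == (0.5,)
        assert curve.fractions == (1.0,)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_ecdf([])

    def test_uniform_grid_close_to_identity(self):
        grid = [(i + 1) / 100 for i in range(100)]
        curve = score_ecdf(grid)
        for x in grid:
            assert abs(curve.at(x) - x) <= 1 / 100 + 1e-12

    def test_matches_brute_force_on_random_draws(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, size=1000)
        curve = score_ecdf(scores.tolist())
        for x in rng.uniform(-0.1, 1.1, size=200):
            brute = np.sum(scores <= x) / len(scores)
            assert curve.at(float(x)) == pytest.approx(brute)

    def test_ties_share_a_step(self):
        curve = score_ecdf([0.2, 0.2, 0.8])
        assert curve.values == (0.2, 0.8)
        assert curve.fractions == (pytest.approx(2 / 3), 1.0)


class TestPopulationBias:
    def test_single_ea_biased_snp(self):
        table = pd.DataFrame([{"gene": "G1", "maf_ea": 12.0, "maf_aa": 2.0}])
        assert population_bias_groups(table) == {"G1": "EA_bias"}

    def test_boundary_is_strict(self):
        table = pd.DataFrame([{"gene": "G1", "maf_ea": 10.0, "maf_aa": 5.0}])
        assert population_bias_groups(table) == {"G1": "no_bias"}

    def test_opposite_biases_in_one_gene(self):
        table = pd.DataFrame(
            [
                {"gene": "G1", "maf_ea": 10.0, "maf_aa": 2.0},
                {"gene": "G1", "maf_ea": 2.0, "maf_aa": 10.0},
            ]
        )
        assert population_bias_groups(table) == {"G1": "EA_AA_bias"}

    def test_missing_both_frequencies_skipped(self):
        table = pd.DataFrame(
            [
                {"gene": "G1", "maf_ea": np.nan, "maf_aa": np.nan},
                {"gene": "G2", "maf_ea": 1.0, "maf_aa": 2.0},
            ]
        )
        assert population_bias_groups(table) == {"G2": "no_bias"}


class TestTTest:
    def test_published_ethnicity_comparison(self):
        """African vs Caucasian per-genome counts: p rounds to 0.18."""
        t, p = two_sample_ttest(AFRICAN_COUNTS, CAUCASIAN_COUNTS)
        assert round(p, 2) == 0.18
        assert t == pytest.approx(1.44, abs=0.005)

    def test_identical_samples(self):
        t, p = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([0, 0], [0, 0])

    def test_sample_size_minimum(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1], [2, 3])

    def test_agrees_with_reference_implementation(self):
        """Pooled t and p match scipy's equal-variance test to 1e-12 on
        100 random instances."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(2, 30))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(2, 30))
            t, p = two_sample_ttest(x, y)
            ref_t, ref_p = sps.ttest_ind(x, y, equal_var=True)
            assert abs(t - ref_t) < 1e-12
            assert abs(p - ref_p) < 1e-12


class TestFeaturePositions:
    def test_relative_position_endpoints(self):
        feature = SequenceFeatureRecord("P1", "DOMAIN", 10, 20)
        assert relative_feature_position(10, feature) == 0.0
        assert relative_feature_position(20, feature) == 1.0
        assert relative_feature_position(15, feature) == 0.5

    def test_length_one_feature(self):
        feature = SequenceFeatureRecord("P1", "MOD_RES", 7, 7)
        assert relative_feature_position(7, feature) == 0.0

    def test_distribution_denominator_is_annotated_only(self, table2_bundle,
                                                        table2_store):
        variants = [v for g in table2_bundle.cohort for v in g.variants]
        frame = feature_type_distribution(variants, table2_store)
        assert frame.attrs["n_annotated"] <= frame.attrs["n_variants"]
        assert 0 < frame.attrs["fraction_annotated"] < 1
        # percentages computed over annotated variants only
        total_pct = sum(
            100.0 * n / frame.attrs["n_annotated"] for n in frame["n_variants"]
        )
        assert total_pct >= 100.0 - 1e-9  # overlaps can push above 100


class TestMafByCategory:
    def test_group_medians_reflect_planted_shift(self, table2_results,
                                                 table2_store):
        """Deleterious associated variants were planted with lower-mean
        frequencies than neutral associated ones."""
        groups = maf_distribution_by_category(table2_results, table2_store)
        summary = maf_group_summary(groups)
        med = {
            (row["group"], row["population"]): row["median"]
            for _, row in summary.iterrows()
        }
        assert med[("2B_3B", "maf_esp_all")] < med[("5", "maf_esp_all")]

    def test_variant_without_frequency_excluded(self, table2_results):
        empty = AnnotationStore()
        groups = maf_distribution_by_category(table2_results, empty)
        assert all(frame.empty for frame in groups.values())

    def test_group_sizes(self, table2_results, table2_store):
        groups = maf_distribution_by_category(table2_results, table2_store)
        # every associated variant has a generated frequency record
        assert len(groups["2B_3B"]) == 30  # |2B ∪ 3B|
        assert len(groups["2A_3A"]) == 200  # |2A ∪ 3A|
        assert len(groups["5"]) == 170


class TestReconciliationProperty:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_holds_on_random_cohorts(self, seed):
        bundle = generate(random_plan(seed, n_subjects=3, scale=6))
        store = bundle.store()
        results = classify_cohort(bundle.cohort, store)
        assert verify_reconciliation(results)
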
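"""AACDS label assignment: closure invariants over all feature
combinations, the worked examples, cohort classification and plan
recovery."""

from __future__ import annotations

import itertools

import pytest

from aacds.classifier import (
    LABELS,
    TIER_PRECEDENCE,
    AacdsFeatures,
    assign_labels,
    classify_cohort,
    classify_variant,
    make_features,
)
from aacds.fixtures import generate, random_plan
from aacds.summaries import category_matrix


def _features(dc: bool, deleterious: bool, dg: bool, tg: bool) -> AacdsFeatures:
    return AacdsFeatures(
        disease_causing=dc,
        consensus_count=4 if deleterious else 1,
        in_disease_gene=dg,
        in_trait_gene=tg,
    )


# Expected label sets for all 16 feature combinations (dc, del, dg, tg).
EXPECTED_LABELS = {
    (False, False, False, False): {"6"},
    (False, False, False, True): {"3A", "5"},
    (False, False, True, False): {"2A", "5"},
    (False, False, True, True): {"2A", "3A", "5"},
    (False, True, False, False): {"4"},
    (False, True, False, True): {"3A", "3B"},
    (False, True, True, False): {"2A", "2B"},
    (False, True, True, True): {"2A", "2B", "3A", "3B"},
    (True, False, False, False): {"1"},
    (True, False, False, True): {"1", "3A", "5"},
    (True, False, True, False): {"1", "2A", "5"},
    (True, False, True, True): {"1", "2A", "3A", "5"},
    (True, True, False, False): {"1", "4"},
    (True, True, False, True): {"1", "3A", "3B"},
    (True, True, True, False): {"1", "2A", "2B"},
    (True, True, True, True): {"1", "2A", "2B", "3A", "3B"},
}


class TestLabelClosure:
    @pytest.mark.parametrize("combo", sorted(EXPECTED_LABELS))
    def test_exhaustive_feature_combinations(self, combo):
        result = assign_labels(_features(*combo))
        assert result.labels == frozenset(EXPECTED_LABELS[combo])

    def test_closure_invariants_hold_for_all_combinations(self):
        """Non-empty labels; 2B ⊆ 2A and 3B ⊆ 3A; 4 and 6 exclude the
        association labels; exactly one exclusive class per variant."""
        for combo in itertools.product([False, True], repeat=4):
            labels = assign_labels(_features(*combo)).labels
            assert labels
            if "2B" in labels:
                assert "2A" in labels
            if "3B" in labels:
                assert "3A" in labels
            if "4" in labels:
                assert not labels & {"2A", "2B", "3A", "3B", "5", "6"}
            if "6" in labels:
                assert labels == {"6"}
            # exclusive partition: at most one of {2B∪3B, 4, 5, 6}, and
            # exactly one unless the only evidence is the documented
            # disease-causing status (labels == {1})
            exclusive = [
                bool(labels & {"2B", "3B"}),
                "4" in labels,
                "5" in labels,
                "6" in labels,
            ]
            if labels == {"1"}:
                assert sum(exclusive) == 0
            else:
                assert sum(exclusive) == 1

    def test_monotone_severity(self):
        """Raising the consensus count or adding an association never
        demotes the primary tier."""
        for combo in itertools.product([False, True], repeat=4):
            dc, deleterious, dg, tg = combo
            base = assign_labels(_features(dc, deleterious, dg, tg))
            rank = TIER_PRECEDENCE.index
            if not deleterious:
                upgraded = assign_labels(_features(dc, True, dg, tg))
                assert rank(upgraded.primary_tier) <= rank(base.primary_tier)
            if not dg:
                upgraded = assign_labels(_features(dc, deleterious, True, tg))
                assert rank(upgraded.primary_tier) <= rank(base.primary_tier)
            if not tg:
                upgraded = assign_labels(_features(dc, deleterious, dg, True))
                assert rank(upgraded.primary_tier) <= rank(base.primary_tier)


class TestReportedLabel:
    @pytest.mark.parametrize(
        "combo,reported",
        [
            ((True, True, True, True), "1/2B/3B"),
            ((False, True, True, True), "2B/3B"),
            ((False, True, False, False), "4"),
            ((False, False, True, True), "5"),
            ((False, False, False, False), "6"),
            ((True, False, True, False), "1"),
        ],
    )
    def test_reported_string(self, combo, reported):
        assert assign_labels(_features(*combo)).reported == reported


class TestMakeFeatures:
    def test_worked_example_has_all_four_features(self, table4_bundle, table4_store):
        """APOE R176C: documented causal, 5 damaging calls, in a gene
        with both disease and trait associations."""
        apoe = next(
            v for v in table4_bundle.cohort[0].variants if v.gene == "APOE"
        )
        features = make_features(apoe, table4_store)
        assert features.disease_causing
        assert features.consensus_count == 5 and features.deleterious
        assert features.in_disease_gene and features.in_trait_gene
        result = classify_variant("T4", apoe, table4_store)
        assert result.result.reported == "1/2B/3B"

    def test_probable_pathogenic_is_not_disease_causing(
        self, table4_bundle, table4_store
    ):
        hnf1a = next(
            v for v in table4_bundle.cohort[0].variants if v.gene == "HNF1A"
        )
        assert not make_features(hnf1a, table4_store).disease_causing

    def test_unannotated_variant_has_no_features(self, table4_bundle):
        from aacds.store import load_store_from_frames

        empty = load_store_from_frames({})
        variant = table4_bundle.cohort[0].variants[0]
        features = make_features(variant, empty)
        assert features == AacdsFeatures(False, 0, False, False)


class TestCohortClassification:
    def test_packaged_cohort_label_totals(self, table2_results):
        """Per-label totals across the packaged 12-genome cohort."""
        matrix = category_matrix(table2_results)
        expected = {"1": 5, "2A": 93, "2B": 14, "3A": 136, "3B": 21,
                    "4": 58, "5": 170, "6": 539}
        for label, total in expected.items():
            assert matrix.loc[label, "total"] == total

    def test_empty_cohort(self, table2_store):
        assert classify_cohort([], table2_store) == []

    @pytest.mark.parametrize("seed", [7, 11])
    def test_plan_recovery_is_exact(self, seed):
        """classify ∘ generate returns the planted per-subject label
        counts exactly, not statistically."""
        plan = random_plan(seed, n_subjects=3, scale=8)
        bundle = generate(plan)
        store = bundle.store()
        known = [
            type(g)(g.subject_id, g.ethnicity, g.sex,
                    [v for v in g.variants if v.variant.rsid is not None])
            for g in bundle.cohort
        ]
        matrix = category_matrix(classify_cohort(known, store))
        for subject in plan.subjects:
            expected = subject.expected_label_counts()
            for label in LABELS:
                assert matrix.loc[label, subject.subject_id] == expected[label], (
                    f"label {label} mismatch for subject {subject.subject_id}"
                )
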
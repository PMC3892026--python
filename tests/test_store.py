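"""Annotation store: loading, validation, lookups, feature overlap and
the write/load round trip."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aacds.store import (
    AnnotationStore,
    StoreLoadError,
    features_at,
    load_store,
    load_store_from_frames,
    lookup_substitution,
    write_store,
)
from aacds.types import PathogenicityStatus, SequenceFeatureRecord


def _frames(**overrides):
    frames = {}
    frames.update(overrides)
    return frames


def test_empty_tables_yield_empty_store():
    store = load_store_from_frames({})
    assert lookup_substitution(store, ("P00001", 1, "A", "C")) == (None, None, None)
    assert features_at(store, "P00001", 1) == []
    assert not store.has_rsid("rs1")


def test_loaded_counts_match_generator_manifest(table2_bundle, table2_store):
    """The loader agrees with the generator's manifest row counts."""
    n = len(table2_bundle.manifest)
    counts = table2_store.report.counts
    assert counts["predictions"] == n
    assert counts["frequencies"] == n
    assert counts["gene_associations"] == n  # one unique gene per variant
    n_known = int((table2_bundle.manifest["rsid"] != ".").sum())
    assert counts["dbsnp"] == n_known
    n_cat1 = int(table2_bundle.manifest["disease_causing"].sum())
    assert counts["pathogenicity"] == n_cat1
    assert not table2_store.report.dropped


def test_worked_example_lookup(table4_store):
    """The APOE R176C row returns its documented causal status and
    disease name, and the residue sits in a REPEAT feature."""
    key = ("P02649", 176, "R", "C")
    profile, record, freq = lookup_substitution(table4_store, key)
    assert record is not None
    assert record.status is PathogenicityStatus.DISEASE_CAUSING
    assert "Lipoprotein glomerulopathy" in record.disease_name
    assert profile is not None and profile.grantham == 180
    assert freq is not None and freq.maf_esp_all == pytest.approx(0.066)
    assert "REPEAT" in {
        f.feature_type for f in features_at(table4_store, "P02649", 176)
    }


def test_probable_status_never_promoted(table4_store):
    """A probable-pathogenic record stays probable."""
    record = table4_store.most_severe_pathogenicity(("Q92765", 324, "R", "G"))
    assert record is not None
    assert record.status is PathogenicityStatus.PROBABLE


def test_partial_annotation_lookup():
    """A key present only in the frequency table yields frequencies but
    no profile and no pathogenicity."""
    frames = {
        "frequencies": pd.DataFrame(
            [
                {
                    "accession": "SYN00001",
                    "residue_index": "5",
                    "ref_aa": "A",
                    "alt_aa": "V",
                    "maf_1kg_eur": "0.01",
                }
            ]
        )
    }
    store = load_store_from_frames(frames)
    profile, record, freq = lookup_substitution(store, ("SYN00001", 5, "A", "V"))
    assert profile is None and record is None
    assert freq is not None and freq.maf_1kg_eur == pytest.approx(0.01)


def test_malformed_key_rejected():
    store = load_store_from_frames({})
    with pytest.raises(ValueError):
        lookup_substitution(store, ("P1", 3, "B", "A"))


def test_missing_mandatory_column_is_hard_error():
    frames = {
        "pathogenicity": pd.DataFrame([{"accession": "P1", "status": "neutral"}])
    }
    with pytest.raises(StoreLoadError, match="mandatory column"):
        load_store_from_frames(frames)


def test_conflicting_duplicate_key_is_hard_error():
    rows = [
        {"accession": "SYN1", "residue_index": "2", "ref_aa": "A", "alt_aa": "V",
         "maf_1kg_eur": "0.01"},
        {"accession": "SYN1", "residue_index": "2", "ref_aa": "A", "alt_aa": "V",
         "maf_1kg_eur": "0.02"},
    ]
    with pytest.raises(StoreLoadError, match="conflicting"):
        load_store_from_frames({"frequencies": pd.DataFrame(rows)})


def test_invalid_rows_dropped_and_reported():
    rows = [
        {"accession": "SYN1", "residue_index": "2", "ref_aa": "A", "alt_aa": "V",
         "maf_1kg_eur": "0.01"},
        {"accession": "SYN1", "residue_index": "0", "ref_aa": "A", "alt_aa": "V",
         "maf_1kg_eur": "0.01"},  # residue < 1
        {"accession": "SYN2", "residue_index": "3", "ref_aa": "A", "alt_aa": "V",
         "maf_1kg_eur": "0.9"},  # violates minor-allele convention
    ]
    store = load_store_from_frames({"frequencies": pd.DataFrame(rows)})
    assert store.report.counts["frequencies"] == 1
    assert len(store.report.dropped) == 2


def test_esp_percent_normalized_to_fraction():
    rows = [
        {"accession": "SYN1", "residue_index": "2", "ref_aa": "A", "alt_aa": "V",
         "maf_esp_ea": "4.8", "maf_esp_aa": "18.5", "maf_esp_all": "9.4"},
    ]
    store = load_store_from_frames({"frequencies": pd.DataFrame(rows)})
    freq = store.frequency(("SYN1", 2, "A", "V"))
    assert freq.maf_esp_ea == pytest.approx(0.048)
    assert freq.maf_esp_aa == pytest.approx(0.185)
    assert freq.maf_esp_all == pytest.approx(0.094)


def test_conflicting_pathogenicity_sources_surfaced():
    """Both records kept, a warning issued, the most severe wins."""
    rows = [
        {"accession": "SYN1", "residue_index": "2", "ref_aa": "A", "alt_aa": "V",
         "status": "neutral", "disease_name": ".", "source": "SwissVar"},
        {"accession": "SYN1", "residue_index": "2", "ref_aa": "A", "alt_aa": "V",
         "status": "probable", "disease_name": "thing", "source": "MSV3d"},
    ]
    store = load_store_from_frames({"pathogenicity": pd.DataFrame(rows)})
    key = ("SYN1", 2, "A", "V")
    assert len(store.pathogenicity_records(key)) == 2
    assert store.most_severe_pathogenicity(key).status is PathogenicityStatus.PROBABLE
    assert any("conflicting" in w for w in store.report.warnings)


@pytest.mark.parametrize(
    "residue,expected",
    [(9, False), (10, True), (15, True), (20, True), (21, False)],
)
def test_feature_overlap_inclusive_bounds(residue, expected):
    feature = SequenceFeatureRecord("P1", "DOMAIN", 10, 20)
    store = AnnotationStore(sequence_features={"P1": (feature,)})
    assert bool(features_at(store, "P1", residue)) is expected


def test_feature_overlap_matches_brute_force():
    """features_at agrees with a naive scan on 1000 random instances."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(0, 8))
        features = tuple(
            SequenceFeatureRecord(
                "PX",
                str(rng.choice(["DOMAIN", "REPEAT", "TRANSMEM"])),
                start := int(rng.integers(1, 200)),
                start + int(rng.integers(0, 50)),
            )
            for _ in range(n)
        )
        store = AnnotationStore(sequence_features={"PX": features})
        residue = int(rng.integers(1, 260))
        expected = [f for f in features if f.start <= residue <= f.end]
        assert features_at(store, "PX", residue) == expected


def test_write_load_round_trip(table2_bundle, table2_store, tmp_path):
    """write_store(load_store(T)) reproduces T's indexed content."""
    write_store(table2_store, tmp_path)
    reloaded = load_store(tmp_path)
    assert reloaded.profiles.keys() == table2_store.profiles.keys()
    for key in table2_store.profiles:
        assert reloaded.profiles[key] == table2_store.profiles[key]
    assert reloaded.frequencies == table2_store.frequencies
    assert reloaded.pathogenicity == table2_store.pathogenicity
    assert reloaded.gene_associations == table2_store.gene_associations
    assert reloaded.sequence_features == table2_store.sequence_features
    assert set(reloaded.dbsnp_entries) == set(table2_store.dbsnp_entries)
    assert reloaded.isoform_map == table2_store.isoform_map
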
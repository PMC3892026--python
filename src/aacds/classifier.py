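"""The Association-Adjusted Consensus Deleterious Scheme (AACDS).

Four boolean features drive the 8-category scheme:

* ``disease_causing`` — a curated record documents the substitution
  itself as causal for a disease (probable-pathogenic records do NOT
  qualify);
* ``deleterious`` — at least 3 of the 6 prediction programs call it
  damaging (the consensus);
* ``in_disease_gene`` / ``in_trait_gene`` — the host gene carries a
  disease or quantitative-trait association.

Category semantics are multi-label: 1, 2A, 2B, 3A and 3B are overlapping
feature labels (2B implies 2A, 3B implies 3A), while 4 (deleterious, no
association), 5 (associated but neutral) and 6 (neither) are mutually
exclusive residual classes.  Every variant therefore falls in exactly one
of the four exclusive classes {2B∪3B, 4, 5, 6}, which is what makes the
per-category counts reconcile with per-genome unique totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .filters import CohortGenome
from .scores import CallThresholds, PredictionProfile, conservation_count, consensus_count
from .store import AnnotationStore
from .types import PathogenicityStatus, ProteinVariant

logger = logging.getLogger(__name__)

LABELS: tuple[str, ...] = ("1", "2A", "2B", "3A", "3B", "4", "5", "6")

#: Reporting order for the severe labels, matching the "1/2B/3B" notation.
SEVERE_LABELS: tuple[str, ...] = ("1", "2B", "3B")

#: Sorting precedence for the single reported tier.
TIER_PRECEDENCE: tuple[str, ...] = ("1", "2B", "3B", "4", "2A", "3A", "5", "6")

#: The priority evaluation space: categories worth manual follow-up.
PRIORITY_LABELS: frozenset[str] = frozenset({"1", "2B", "3B", "4"})

CONSENSUS_MIN = 3


@dataclass(frozen=True)
class AacdsFeatures:
    """The four classification features plus the raw consensus count."""

    disease_causing: bool
    consensus_count: int
    in_disease_gene: bool
    in_trait_gene: bool

    def __post_init__(self) -> None:
        if not 0 <= self.consensus_count <= 6:
            raise ValueError("consensus_count must be in 0..6")

    @property
    def deleterious(self) -> bool:
        return self.consensus_count >= CONSENSUS_MIN


@dataclass(frozen=True)
class AacdsResult:
    """Label set, reported label string and single sorting tier."""

    labels: frozenset[str]
    reported: str
    primary_tier: str

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("labels must be non-empty")
        unknown = self.labels - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")


def make_features(
    variant: ProteinVariant,
    store: AnnotationStore,
    thresholds: CallThresholds | None = None,
) -> AacdsFeatures:
    """Assemble the AACDS features for one variant from the store.

    A missing annotation record always maps to False — absence of
    evidence never asserts an association.  When curated sources
    conflict, the most severe status is used (a "probable" record is
    never promoted to disease-causing).
    """
    thresholds = thresholds or CallThresholds()
    record = store.most_severe_pathogenicity(variant.key)
    disease_causing = (
        record is not None
        and record.status is PathogenicityStatus.DISEASE_CAUSING
    )
    profile = store.profile(variant.key)
    count = 0 if profile is None else consensus_count(profile, thresholds)
    association = store.gene_association(variant.gene)
    in_disease_gene = association is not None and bool(association.disease_assoc)
    in_trait_gene = association is not None and bool(association.trait_assoc)
    return AacdsFeatures(
        disease_causing=disease_causing,
        consensus_count=count,
        in_disease_gene=in_disease_gene,
        in_trait_gene=in_trait_gene,
    )


def assign_labels(features: AacdsFeatures) -> AacdsResult:
    """Map the feature vector onto the multi-label category set.

    Reported label: the "/"-joined severe labels (1, 2B, 3B) when any
    apply, otherwise the single exclusive residual class (4, 5 or 6).
    """
    dc = features.disease_causing
    deleterious = features.deleterious
    dg = features.in_disease_gene
    tg = features.in_trait_gene

    labels: set[str] = set()
    if dc:
        labels.add("1")
    if dg:
        labels.add("2A")
        if deleterious:
            labels.add("2B")
    if tg:
        labels.add("3A")
        if deleterious:
            labels.add("3B")
    if deleterious and not dg and not tg:
        labels.add("4")
    if (dg or tg) and not deleterious:
        labels.add("5")
    if not labels:
        labels.add("6")

    if labels == {"1", "4"}:
        logger.info(
            "documented disease-causing variant without any gene-level "
            "association record: labels {1, 4}"
        )

    severe = [label for label in SEVERE_LABELS if label in labels]
    if severe:
        reported = "/".join(severe)
    else:
        reported = next(label for label in ("4", "5", "6") if label in labels)
    primary_tier = next(label for label in TIER_PRECEDENCE if label in labels)
    return AacdsResult(
        labels=frozenset(labels), reported=reported, primary_tier=primary_tier
    )


@dataclass(frozen=True)
class ClassifiedVariant:
    """One variant with its features, labels and score counts."""

    subject_id: str
    variant: ProteinVariant
    features: AacdsFeatures
    result: AacdsResult
    conservation_count: int
    profile: Optional[PredictionProfile]
    ethnicity: Optional[str] = None
    sex: Optional[str] = None


def classify_variant(
    subject_id: str,
    variant: ProteinVariant,
    store: AnnotationStore,
    thresholds: CallThresholds | None = None,
    ethnicity: Optional[str] = None,
    sex: Optional[str] = None,
) -> ClassifiedVariant:
    thresholds = thresholds or CallThresholds()
    features = make_features(variant, store, thresholds)
    profile = store.profile(variant.key)
    return ClassifiedVariant(
        subject_id=subject_id,
        variant=variant,
        features=features,
        result=assign_labels(features),
        conservation_count=(
            0 if profile is None else conservation_count(profile, thresholds)
        ),
        profile=profile,
        ethnicity=ethnicity,
        sex=sex,
    )


def classify_cohort(
    cohort: Iterable[CohortGenome],
    store: AnnotationStore,
    thresholds: CallThresholds | None = None,
) -> list[ClassifiedVariant]:
    """Classify every variant of every genome; order is stable (cohort
    order, then each genome's variant order)."""
    thresholds = thresholds or CallThresholds()
    return [
        classify_variant(
            genome.subject_id,
            variant,
            store,
            thresholds,
            ethnicity=genome.ethnicity,
            sex=genome.sex,
        )
        for genome in cohort
        for variant in genome.variants
    ]
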
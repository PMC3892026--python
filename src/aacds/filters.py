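"""Selection of the analysis set: homozygous rare missense variants,
partitioned into known (present in the dbSNP snapshot) and private.

"Rare" means a matched-population 1000 Genomes minor allele frequency
strictly below the threshold (default 10%).  A variant absent from the
frequency panel has, by definition, never been observed there and is
retained.  Quality filtering applies only when a variant carries a
quality value, because annotation-table inputs lack one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .store import AnnotationStore
from .types import ProteinVariant, Zygosity

logger = logging.getLogger(__name__)

ETHNICITIES = ("African", "Caucasian", "other")


@dataclass
class CohortGenome:
    """One subject's genome: identity plus its missense variant list."""

    subject_id: str
    ethnicity: str
    sex: str
    variants: list[ProteinVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"unknown ethnicity {self.ethnicity!r}; expected one of "
                f"{ETHNICITIES}"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Rare-variant filter settings.

    ``population_mode`` decides which 1000 Genomes column bounds the MAF:
    ``ethnicity_matched`` uses the subject's own population (the default),
    ``any`` keeps a variant rare in at least one population, ``all``
    requires rarity in every population with data.
    """

    maf_threshold: float = 0.10
    qual_min: float = 20.0
    population_mode: str = "ethnicity_matched"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in (0, 0.5]")
        if self.population_mode not in ("ethnicity_matched", "any", "all"):
            raise ValueError(
                f"unknown population_mode {self.population_mode!r}"
            )


def _population_mafs(
    variant: ProteinVariant,
    ethnicity: str,
    config: FilterConfig,
    store: AnnotationStore,
) -> list[float]:
    """1000 Genomes MAFs relevant under the configured population mode.

    Empty list = no panel data = treated as never observed (frequency 0).
    """
    freq = store.frequency(variant.key)
    if freq is None:
        return []
    panel = {"Caucasian": freq.maf_1kg_eur, "African": freq.maf_1kg_afr}
    if config.population_mode == "ethnicity_matched":
        if ethnicity not in panel:
            raise ValueError(
                f"ethnicity {ethnicity!r} has no matched frequency panel; "
                "use population_mode='any' or 'all' instead"
            )
        value = panel[ethnicity]
        return [] if value is None else [value]
    values = [value for value in panel.values() if value is not None]
    return values


def _is_rare(
    variant: ProteinVariant,
    ethnicity: str,
    config: FilterConfig,
    store: AnnotationStore,
) -> bool:
    mafs = _population_mafs(variant, ethnicity, config, store)
    if not mafs:
        return True
    if config.population_mode == "any":
        return any(maf < config.maf_threshold for maf in mafs)
    # ethnicity_matched has a single value; "all" requires every panel
    return all(maf < config.maf_threshold for maf in mafs)


def select_homozygous_missense(
    genome: CohortGenome,
    config: FilterConfig | None = None,
    store: AnnotationStore | None = None,
) -> list[ProteinVariant]:
    """Retain homozygous-alternate missense variants that pass quality
    (when present) and the strict matched-population MAF < threshold.

    Output preserves input order.  Hemizygous-style chromosome X calls
    arrive already encoded as ``hom_alt`` by the VCF reader and are kept.
    """
    config = config or FilterConfig()
    store = store or AnnotationStore()
    kept: list[ProteinVariant] = []
    for variant in genome.variants:
        genomic = variant.variant
        if genomic.zygosity is not Zygosity.HOM_ALT:
            continue
        if genomic.qual is not None and genomic.qual < config.qual_min:
            continue
        if not _is_rare(variant, genome.ethnicity, config, store):
            continue
        kept.append(variant)
    return kept


def partition_known_private(
    variants: Iterable[ProteinVariant], store: AnnotationStore
) -> tuple[list[ProteinVariant], list[ProteinVariant]]:
    """Split variants into (known, private) by dbSNP snapshot membership.

    Membership is decided by rsID presence; a variant without an rsID is
    looked up by genomic position.  The two lists are disjoint and
    together exhaust the input.
    """
    known: list[ProteinVariant] = []
    private: list[ProteinVariant] = []
    for variant in variants:
        genomic = variant.variant
        if genomic.rsid:
            in_dbsnp = store.has_rsid(genomic.rsid)
        else:
            in_dbsnp = store.has_position(genomic.chrom, genomic.pos)
        (known if in_dbsnp else private).append(variant)
    return known, private


def per_genome_counts(
    cohort: Iterable[CohortGenome], store: AnnotationStore
) -> pd.DataFrame:
    """Per-subject counts of known and private variants and their genes.

    Counting is per genome: a variant shared by two subjects counts once
    in each (cohort totals are sums of per-genome counts, with no
    cross-genome deduplication).
    """
    rows = []
    for genome in cohort:
        known, private = partition_known_private(genome.variants, store)
        rows.append(
            {
                "subject_id": genome.subject_id,
                "ethnicity": genome.ethnicity,
                "sex": genome.sex,
                "n_known": len(known),
                "n_known_genes": len({v.gene for v in known}),
                "n_private": len(private),
                "n_private_genes": len({v.gene for v in private}),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "ethnicity",
            "sex",
            "n_known",
            "n_known_genes",
            "n_private",
            "n_private_genes",
        ],
    )
    return frame
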
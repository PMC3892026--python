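"""Core domain types shared across the AACDS pipeline.

A substitution is identified at the protein level by the key
``(accession, residue_index, ref_aa, alt_aa)``: the curated pathogenicity
databases the scheme draws on key their records on protein identity, so
genomic coordinates are carried along but never used as a join key.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: The 20 standard one-letter amino acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Nucleotide alphabet accepted for alleles.
NUCLEOTIDES = frozenset("ACGT")

SubstitutionKey = tuple[str, int, str, str]


class Zygosity(str, enum.Enum):
    HOM_ALT = "hom_alt"
    HET = "het"
    HOM_REF = "hom_ref"


class PathogenicityStatus(str, enum.Enum):
    """Curated variant status, ordered from most to least severe."""

    DISEASE_CAUSING = "disease_causing"
    PROBABLE = "probable"
    UNCLASSIFIED = "unclassified"
    NEUTRAL = "neutral"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


_SEVERITY = {
    PathogenicityStatus.DISEASE_CAUSING: 3,
    PathogenicityStatus.PROBABLE: 2,
    PathogenicityStatus.UNCLASSIFIED: 1,
    PathogenicityStatus.NEUTRAL: 0,
}


def validate_amino_acid(aa: str, *, context: str = "amino acid") -> str:
    if aa not in STANDARD_AA:
        raise ValueError(f"non-standard {context}: {aa!r}")
    return aa


@dataclass(frozen=True)
class GenomicVariant:
    """One biallelic SNV in genomic coordinates (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    zygosity: Zygosity = Zygosity.HOM_ALT
    qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref, self.alt):
            if not set(allele) <= NUCLEOTIDES:
                raise ValueError(f"allele {allele!r} not over {{A,C,G,T}}")


@dataclass(frozen=True)
class ProteinVariant:
    """A missense substitution with both genomic and protein coordinates."""

    variant: GenomicVariant
    gene: str
    accession: str
    transcript: str
    residue_index: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        validate_amino_acid(self.ref_aa, context="ref_aa")
        validate_amino_acid(self.alt_aa, context="alt_aa")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ (missense)")

    @property
    def key(self) -> SubstitutionKey:
        return (self.accession, self.residue_index, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class PathogenicityRecord:
    """Curated disease status for one substitution (MSV3d/SwissVar style)."""

    key: SubstitutionKey
    status: PathogenicityStatus
    disease_name: Optional[str] = None
    source: str = "other"

    def __post_init__(self) -> None:
        if (
            self.status is PathogenicityStatus.DISEASE_CAUSING
            and not self.disease_name
        ):
            raise ValueError("disease_causing records require a disease_name")


@dataclass(frozen=True)
class GeneAssociationRecord:
    """Gene-level disease and trait associations (GWAS/OMIM style)."""

    gene: str
    disease_assoc: tuple[str, ...] = ()
    trait_assoc: tuple[str, ...] = ()
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, values in (
            ("disease_assoc", self.disease_assoc),
            ("trait_assoc", self.trait_assoc),
        ):
            if len(set(values)) != len(values):
                raise ValueError(f"{name} contains duplicates: {values}")


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Minor allele frequencies, all stored as fractions in [0, 0.5].

    ESP columns are published as percentages; the loader divides them by
    100 so every in-memory frequency shares one scale.
    """

    maf_1kg_eur: Optional[float] = None
    maf_1kg_afr: Optional[float] = None
    maf_esp_ea: Optional[float] = None
    maf_esp_aa: Optional[float] = None
    maf_esp_all: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "maf_1kg_eur",
            "maf_1kg_afr",
            "maf_esp_ea",
            "maf_esp_aa",
            "maf_esp_all",
        ):
            value = getattr(self, name)
            if value is None:
                continue
            if not 0.0 <= value <= 0.5:
                raise ValueError(
                    f"{name}={value} violates the minor-allele convention "
                    "(fraction in [0, 0.5])"
                )


@dataclass(frozen=True)
class SequenceFeatureRecord:
    """A curated protein region (TRANSMEM, DOMAIN, REPEAT, ...)."""

    accession: str
    feature_type: str
    start: int
    end: int
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"feature bounds must satisfy 1 <= start <= end, got "
                f"[{self.start}, {self.end}]"
            )

    def contains(self, residue_index: int) -> bool:
        """Inclusive interval membership."""
        return self.start <= residue_index <= self.end


# Sentinel used by lookups for absent annotation: explicit, never a default
# score.  ``None`` is reserved for "field not applicable".
MISSING = None
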
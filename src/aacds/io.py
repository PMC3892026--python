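"""Cohort input/output: the delimited variant table and the VCF path.

The native cohort format is one TSV with a header row and one row per
variant, carrying subject identity, genomic coordinates and the protein
mapping.  A minimal VCF route is also provided: only CHROM, POS, ID,
REF, ALT, QUAL and the GT of a single sample are read, multi-allelic
records are decomposed into biallelic variants, and the protein mapping
is joined from a site-map table keyed on (chrom, pos, ref, alt).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import pysam

from .filters import CohortGenome
from .types import GenomicVariant, ProteinVariant, Zygosity

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id",
    "ethnicity",
    "sex",
    "chrom",
    "pos",
    "ref",
    "alt",
    "rsid",
    "zygosity",
    "qual",
    "gene",
    "accession",
    "transcript",
    "residue_index",
    "ref_aa",
    "alt_aa",
]

SITE_MAP_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "accession",
    "transcript",
    "residue_index",
    "ref_aa",
    "alt_aa",
]

MISSING_TOKEN = "."


def _opt(value: object) -> Optional[str]:
    if value is None or pd.isna(value) or value in ("", MISSING_TOKEN):
        return None
    return str(value)


def read_cohort_tsv(path: str | Path) -> list[CohortGenome]:
    """Read a cohort variant table into per-subject genomes.

    Subject order and per-subject variant order follow file order.
    """
    frame = pd.read_csv(
        Path(path), sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    for column in COHORT_COLUMNS:
        if column not in frame.columns:
            raise ValueError(f"cohort table is missing column {column!r}")
    genomes: dict[str, CohortGenome] = {}
    for _, row in frame.iterrows():
        subject_id = str(row["subject_id"])
        if subject_id not in genomes:
            genomes[subject_id] = CohortGenome(
                subject_id=subject_id,
                ethnicity=str(row["ethnicity"]),
                sex=str(row["sex"]),
            )
        qual = _opt(row["qual"])
        variant = ProteinVariant(
            variant=GenomicVariant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                rsid=_opt(row["rsid"]),
                zygosity=Zygosity(str(row["zygosity"])),
                qual=None if qual is None else float(qual),
            ),
            gene=str(row["gene"]),
            accession=str(row["accession"]),
            transcript=str(row["transcript"]),
            residue_index=int(row["residue_index"]),
            ref_aa=str(row["ref_aa"]),
            alt_aa=str(row["alt_aa"]),
        )
        genomes[subject_id].variants.append(variant)
    return list(genomes.values())


def write_cohort_tsv(cohort: list[CohortGenome], path: str | Path) -> None:
    rows = []
    for genome in cohort:
        for variant in genome.variants:
            genomic = variant.variant
            rows.append(
                {
                    "subject_id": genome.subject_id,
                    "ethnicity": genome.ethnicity,
                    "sex": genome.sex,
                    "chrom": genomic.chrom,
                    "pos": str(genomic.pos),
                    "ref": genomic.ref,
                    "alt": genomic.alt,
                    "rsid": genomic.rsid or MISSING_TOKEN,
                    "zygosity": genomic.zygosity.value,
                    "qual": (
                        MISSING_TOKEN
                        if genomic.qual is None
                        else format(genomic.qual, "g")
                    ),
                    "gene": variant.gene,
                    "accession": variant.accession,
                    "transcript": variant.transcript,
                    "residue_index": str(variant.residue_index),
                    "ref_aa": variant.ref_aa,
                    "alt_aa": variant.alt_aa,
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def _zygosity_from_gt(alleles: tuple, alt_index: int, chrom: str) -> Optional[Zygosity]:
    """Genotype of one decomposed ALT allele.

    1/1 after decomposition is hom_alt; a hemizygous male X call (single
    allele) carrying the alternate is treated as hom_alt and logged.
    """
    if alleles is None or all(a is None for a in alleles):
        return None
    calls = [a for a in alleles if a is not None]
    n_alt = sum(1 for a in calls if a == alt_index)
    if len(calls) == 1:
        if n_alt == 1:
            logger.info("hemizygous alternate call on %s treated as hom_alt", chrom)
            return Zygosity.HOM_ALT
        return Zygosity.HOM_REF
    if n_alt == len(calls):
        return Zygosity.HOM_ALT
    if n_alt > 0:
        return Zygosity.HET
    return Zygosity.HOM_REF


def read_vcf(
    path: str | Path,
    site_map: pd.DataFrame | str | Path,
    subject_id: str,
    ethnicity: str,
    sex: str = "unknown",
) -> CohortGenome:
    """Read a single-sample VCF and join the protein mapping.

    Records without a site-map entry (non-missense or unmapped) are
    skipped.  Multi-allelic records are decomposed into biallelic
    variants before genotype interpretation.
    """
    if not isinstance(site_map, pd.DataFrame):
        site_map = pd.read_csv(
            Path(site_map), sep="\t", dtype=str, keep_default_na=False, na_values=[]
        )
    for column in SITE_MAP_COLUMNS:
        if column not in site_map.columns:
            raise ValueError(f"site map is missing column {column!r}")
    mapping = {
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"])): r
        for _, r in site_map.iterrows()
    }

    genome = CohortGenome(subject_id=subject_id, ethnicity=ethnicity, sex=sex)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"expected a single-sample VCF, found {len(samples)} samples"
            )
        sample = samples[0]
        for record in vcf:
            for alt_index, alt in enumerate(record.alts or (), start=1):
                key = (str(record.chrom), int(record.pos), str(record.ref), str(alt))
                row = mapping.get(key)
                if row is None:
                    continue
                zygosity = _zygosity_from_gt(
                    record.samples[sample].get("GT"), alt_index, str(record.chrom)
                )
                if zygosity is None:
                    continue
                genome.variants.append(
                    ProteinVariant(
                        variant=GenomicVariant(
                            chrom=str(record.chrom),
                            pos=int(record.pos),
                            ref=str(record.ref),
                            alt=str(alt),
                            rsid=record.id,
                            zygosity=zygosity,
                            qual=(
                                None if record.qual is None else float(record.qual)
                            ),
                        ),
                        gene=str(row["gene"]),
                        accession=str(row["accession"]),
                        transcript=str(row["transcript"]),
                        residue_index=int(row["residue_index"]),
                        ref_aa=str(row["ref_aa"]),
                        alt_aa=str(row["alt_aa"]),
                    )
                )
    return genome
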
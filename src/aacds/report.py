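"""Per-variant AACDS reports and the classification results table.

One row/section per variant, ordered by priority tier then genomic
position, with every displayed number traceable to a store entry or a
computed operation.  The thresholds in force are echoed into every
header so a report is self-describing.  HTML, TSV and plain-text
renderings carry identical values.
"""

from __future__ import annotations

import html as _html
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .classifier import (
    TIER_PRECEDENCE,
    AacdsFeatures,
    AacdsResult,
    ClassifiedVariant,
)
from .scores import ALGORITHMS, Call, CallThresholds, call_deleterious
from .store import AnnotationStore, features_at
from .types import GenomicVariant, ProteinVariant, Zygosity

FORMATS = ("tsv", "text", "html")

RESULT_COLUMNS = [
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
    "aa_change",
    "labels",
    "reported",
    "primary_tier",
    "disease_causing",
    "consensus_count",
    "conservation_count",
    "in_disease_gene",
    "in_trait_gene",
    "grantham",
    "maf_esp_ea_percent",
    "maf_esp_aa_percent",
    "maf_esp_all_percent",
    "pathogenicity_status",
    "disease_name",
    "disease_associations",
    "trait_associations",
    "sequence_features",
] + [f"{alg}_call" for alg in ALGORITHMS]

MISSING_TOKEN = "."


def _fmt(value: object) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _tier_rank(tier: str) -> int:
    return TIER_PRECEDENCE.index(tier)


def _chrom_rank(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)  # X, Y, MT after numeric chromosomes


def sort_records(
    records: Iterable[ClassifiedVariant],
) -> list[ClassifiedVariant]:
    """Priority tier first, then genomic position."""
    return sorted(
        records,
        key=lambda r: (
            _tier_rank(r.result.primary_tier),
            _chrom_rank(r.variant.variant.chrom),
            r.variant.variant.pos,
        ),
    )


def build_report_frame(
    records: Iterable[ClassifiedVariant],
    store: AnnotationStore,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Assemble the full per-variant report table (sorted)."""
    thresholds = thresholds or CallThresholds()
    rows = []
    for record in sort_records(records):
        variant = record.variant
        genomic = variant.variant
        freq = store.frequency(variant.key)
        patho = store.most_severe_pathogenicity(variant.key)
        assoc = store.gene_association(variant.gene)
        overlaps = features_at(store, variant.accession, variant.residue_index)
        profile = record.profile
        row = {
            "subject_id": record.subject_id,
            "ethnicity": _fmt(record.ethnicity),
            "sex": _fmt(record.sex),
            "chrom": genomic.chrom,
            "pos": _fmt(genomic.pos),
            "ref": genomic.ref,
            "alt": genomic.alt,
            "rsid": _fmt(genomic.rsid),
            "zygosity": genomic.zygosity.value,
            "qual": _fmt(genomic.qual),
            "gene": variant.gene,
            "accession": variant.accession,
            "transcript": variant.transcript,
            "residue_index": _fmt(variant.residue_index),
            "ref_aa": variant.ref_aa,
            "alt_aa": variant.alt_aa,
            "aa_change": f"{variant.ref_aa}{variant.residue_index}{variant.alt_aa}",
            "labels": "|".join(sorted(record.result.labels)),
            "reported": record.result.reported,
            "primary_tier": record.result.primary_tier,
            "disease_causing": _fmt(record.features.disease_causing),
            "consensus_count": _fmt(record.features.consensus_count),
            "conservation_count": _fmt(record.conservation_count),
            "in_disease_gene": _fmt(record.features.in_disease_gene),
            "in_trait_gene": _fmt(record.features.in_trait_gene),
            "grantham": _fmt(None if profile is None else profile.grantham),
            "maf_esp_ea_percent": _fmt(
                None if freq is None or freq.maf_esp_ea is None
                else round(100 * freq.maf_esp_ea, 4)
            ),
            "maf_esp_aa_percent": _fmt(
                None if freq is None or freq.maf_esp_aa is None
                else round(100 * freq.maf_esp_aa, 4)
            ),
            "maf_esp_all_percent": _fmt(
                None if freq is None or freq.maf_esp_all is None
                else round(100 * freq.maf_esp_all, 4)
            ),
            "pathogenicity_status": _fmt(
                None if patho is None else patho.status.value
            ),
            "disease_name": _fmt(None if patho is None else patho.disease_name),
            "disease_associations": (
                "|".join(assoc.disease_assoc) if assoc and assoc.disease_assoc
                else MISSING_TOKEN
            ),
            "trait_associations": (
                "|".join(assoc.trait_assoc) if assoc and assoc.trait_assoc
                else MISSING_TOKEN
            ),
            "sequence_features": (
                "|".join(f.feature_type for f in overlaps)
                if overlaps
                else MISSING_TOKEN
            ),
        }
        for alg in ALGORITHMS:
            if profile is None:
                row[f"{alg}_call"] = Call.MISSING.value
            else:
                row[f"{alg}_call"] = call_deleterious(
                    alg, profile.entry(alg), thresholds
                ).value
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def threshold_header_lines(thresholds: CallThresholds) -> list[str]:
    """Provenance header: every cutoff in force, one per line."""
    lines = ["# AACDS report", "# coordinates: genomic 1-based; protein residues 1-based; intervals inclusive"]
    for key, value in sorted(thresholds.as_dict().items()):
        lines.append(f"# threshold {key} = {value}")
    return lines


def render_report(
    records: Iterable[ClassifiedVariant],
    store: AnnotationStore,
    format: str = "tsv",
    thresholds: CallThresholds | None = None,
) -> str:
    """Render the report in ``tsv``, ``text`` or ``html``."""
    if format not in FORMATS:
        raise ValueError(f"unknown report format {format!r}; expected {FORMATS}")
    thresholds = thresholds or CallThresholds()
    frame = build_report_frame(records, store, thresholds)
    header = threshold_header_lines(thresholds)

    if format == "tsv":
        body = frame.to_csv(sep="\t", index=False)
        return "\n".join(header) + "\n" + body

    if format == "text":
        blocks = ["\n".join(header), ""]
        for _, row in frame.iterrows():
            blocks.append(
                f"== {row['gene']} {row['aa_change']} "
                f"({row['chrom']}:{row['pos']} {row['ref']}>{row['alt']}) =="
            )
            for column in RESULT_COLUMNS:
                blocks.append(f"  {column}: {row[column]}")
            blocks.append("")
        return "\n".join(blocks)

    # html
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>AACDS report</title></head><body>",
        "<h1>AACDS report</h1>",
        "<pre>" + _html.escape("\n".join(header)) + "</pre>",
        "<table border='1'>",
        "<tr>" + "".join(f"<th>{_html.escape(c)}</th>" for c in RESULT_COLUMNS) + "</tr>",
    ]
    for _, row in frame.iterrows():
        parts.append(
            "<tr>"
            + "".join(
                f"<td>{_html.escape(str(row[c]))}</td>" for c in RESULT_COLUMNS
            )
            + "</tr>"
        )
    parts.append("</table></body></html>")
    return "\n".join(parts)


def write_results_tsv(
    records: Iterable[ClassifiedVariant],
    store: AnnotationStore,
    path: str | Path,
    thresholds: CallThresholds | None = None,
) -> None:
    Path(path).write_text(
        render_report(records, store, format="tsv", thresholds=thresholds)
    )


def read_results_tsv(
    path: str | Path, store: AnnotationStore
) -> list[ClassifiedVariant]:
    """Reconstruct classified records from a results TSV (round-trips
    :func:`write_results_tsv` up to the profile reference)."""
    frame = pd.read_csv(
        Path(path),
        sep="\t",
        dtype=str,
        comment="#",
        keep_default_na=False,
        na_values=[],
    )
    records = []
    for _, row in frame.iterrows():
        variant = ProteinVariant(
            variant=GenomicVariant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                rsid=None if row["rsid"] == MISSING_TOKEN else str(row["rsid"]),
                zygosity=Zygosity(str(row["zygosity"])),
                qual=(
                    None if row["qual"] == MISSING_TOKEN else float(row["qual"])
                ),
            ),
            gene=str(row["gene"]),
            accession=str(row["accession"]),
            transcript=str(row["transcript"]),
            residue_index=int(row["residue_index"]),
            ref_aa=str(row["ref_aa"]),
            alt_aa=str(row["alt_aa"]),
        )
        features = AacdsFeatures(
            disease_causing=row["disease_causing"] == "1",
            consensus_count=int(row["consensus_count"]),
            in_disease_gene=row["in_disease_gene"] == "1",
            in_trait_gene=row["in_trait_gene"] == "1",
        )
        result = AacdsResult(
            labels=frozenset(str(row["labels"]).split("|")),
            reported=str(row["reported"]),
            primary_tier=str(row["primary_tier"]),
        )
        records.append(
            ClassifiedVariant(
                subject_id=str(row["subject_id"]),
                variant=variant,
                features=features,
                result=result,
                conservation_count=int(row["conservation_count"]),
                profile=store.profile(variant.key),
                ethnicity=(
                    None if row["ethnicity"] == MISSING_TOKEN
                    else str(row["ethnicity"])
                ),
                sex=None if row["sex"] == MISSING_TOKEN else str(row["sex"]),
            )
        )
    return records
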
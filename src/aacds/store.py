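"""Local annotation store: load, validate, index and write the TSV tables
that stand in for dbNSFP (prediction scores), MSV3d/SwissVar (curated
pathogenicity), GWAS/OMIM gene lists, allele-frequency panels, the dbSNP
rsID snapshot and UniProt sequence-feature records.

Every table is delimiter-separated text with one header row; missing
cells use the ``.`` token (dbNSFP convention) and always map to
"missing", never to a default score.  Lookups are keyed on the protein
substitution ``(accession, residue_index, ref_aa, alt_aa)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .grantham import distance as grantham_distance
from .scores import (
    ALGORITHMS,
    CONSERVATION_INDICATORS,
    AlgorithmEntry,
    PredictionProfile,
)
from .types import (
    STANDARD_AA,
    AlleleFrequencySet,
    GeneAssociationRecord,
    PathogenicityRecord,
    PathogenicityStatus,
    SequenceFeatureRecord,
    SubstitutionKey,
)

logger = logging.getLogger(__name__)

#: Conventional file names inside a store directory.
TABLE_FILES = {
    "predictions": "predictions.tsv",
    "pathogenicity": "pathogenicity.tsv",
    "gene_associations": "gene_associations.tsv",
    "frequencies": "frequencies.tsv",
    "sequence_features": "sequence_features.tsv",
    "dbsnp": "dbsnp.tsv",
    "isoform_map": "isoform_map.tsv",
}

KEY_COLUMNS = ["accession", "residue_index", "ref_aa", "alt_aa"]

MANDATORY_COLUMNS = {
    "predictions": KEY_COLUMNS,
    "pathogenicity": KEY_COLUMNS + ["status"],
    "gene_associations": ["gene"],
    "frequencies": KEY_COLUMNS,
    "sequence_features": ["accession", "feature_type", "start", "end"],
    "dbsnp": ["rsid"],
    "isoform_map": ["gene", "accession", "transcript", "major_isoform"],
}

MISSING_TOKEN = "."


class StoreLoadError(RuntimeError):
    """Hard loading failure: missing column, conflicting duplicate key."""


@dataclass
class LoadReport:
    """Per-table accounting of what was loaded and what was dropped."""

    counts: dict[str, int] = field(default_factory=dict)
    dropped: list[tuple[str, int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def drop(self, table: str, row: int, reason: str) -> None:
        self.dropped.append((table, row, reason))

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise StoreLoadError(f"{table} table not found: {path}")
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    for column in MANDATORY_COLUMNS[table]:
        if column not in frame.columns:
            raise StoreLoadError(
                f"table {path.name} is missing mandatory column {column!r}"
            )
    return frame


def _cell(row: pd.Series, column: str) -> Optional[str]:
    value = row.get(column)
    if value is None or value == "" or value == MISSING_TOKEN:
        return None
    return str(value)


def _float_cell(row: pd.Series, column: str) -> Optional[float]:
    value = _cell(row, column)
    return None if value is None else float(value)


def _parse_key(row: pd.Series) -> SubstitutionKey:
    accession = _cell(row, "accession")
    residue = _cell(row, "residue_index")
    ref_aa = _cell(row, "ref_aa")
    alt_aa = _cell(row, "alt_aa")
    if accession is None or residue is None or ref_aa is None or alt_aa is None:
        raise ValueError("incomplete substitution key")
    index = int(residue)
    if index < 1:
        raise ValueError(f"residue_index {index} < 1")
    for aa in (ref_aa, alt_aa):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid {aa!r}")
    return (accession, index, ref_aa, alt_aa)


def validate_key(key: SubstitutionKey) -> SubstitutionKey:
    accession, residue_index, ref_aa, alt_aa = key
    if residue_index < 1:
        raise ValueError(f"residue_index {residue_index} < 1")
    for aa in (ref_aa, alt_aa):
        if aa not in STANDARD_AA:
            raise ValueError(f"malformed substitution key: amino acid {aa!r}")
    return key


@dataclass
class AnnotationStore:
    """Indexed, read-only view over the annotation tables."""

    profiles: dict[SubstitutionKey, PredictionProfile] = field(default_factory=dict)
    pathogenicity: dict[SubstitutionKey, tuple[PathogenicityRecord, ...]] = field(
        default_factory=dict
    )
    frequencies: dict[SubstitutionKey, AlleleFrequencySet] = field(
        default_factory=dict
    )
    gene_associations: dict[str, GeneAssociationRecord] = field(default_factory=dict)
    sequence_features: dict[str, tuple[SequenceFeatureRecord, ...]] = field(
        default_factory=dict
    )
    dbsnp_entries: tuple[tuple[str, Optional[str], Optional[int]], ...] = ()
    isoform_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    schema_version: str = "1"
    report: LoadReport = field(default_factory=LoadReport)

    # -- lookups ---------------------------------------------------------

    def profile(self, key: SubstitutionKey) -> Optional[PredictionProfile]:
        return self.profiles.get(validate_key(key))

    def pathogenicity_records(
        self, key: SubstitutionKey
    ) -> tuple[PathogenicityRecord, ...]:
        """All curated records for a key; sources may disagree."""
        return self.pathogenicity.get(validate_key(key), ())

    def most_severe_pathogenicity(
        self, key: SubstitutionKey
    ) -> Optional[PathogenicityRecord]:
        """Most severe record when sources conflict (never promotes)."""
        records = self.pathogenicity_records(key)
        if not records:
            return None
        return max(records, key=lambda r: r.status.severity)

    def frequency(self, key: SubstitutionKey) -> Optional[AlleleFrequencySet]:
        return self.frequencies.get(validate_key(key))

    def gene_association(self, gene: str) -> Optional[GeneAssociationRecord]:
        return self.gene_associations.get(gene)

    @property
    def dbsnp_rsids(self) -> frozenset[str]:
        return frozenset(entry[0] for entry in self.dbsnp_entries)

    @property
    def dbsnp_positions(self) -> frozenset[tuple[str, int]]:
        return frozenset(
            (entry[1], entry[2])
            for entry in self.dbsnp_entries
            if entry[1] is not None and entry[2] is not None
        )

    def has_rsid(self, rsid: str) -> bool:
        return rsid in self.dbsnp_rsids

    def has_position(self, chrom: str, pos: int) -> bool:
        return (str(chrom), int(pos)) in self.dbsnp_positions


def lookup_substitution(
    store: AnnotationStore, key: SubstitutionKey
) -> tuple[
    Optional[PredictionProfile],
    Optional[PathogenicityRecord],
    Optional[AlleleFrequencySet],
]:
    """Pure lookup of (profile, most-severe pathogenicity, frequencies).

    Any component absent from its table is returned as ``None``.
    """
    validate_key(key)
    return (
        store.profile(key),
        store.most_severe_pathogenicity(key),
        store.frequency(key),
    )


def features_at(
    store: AnnotationStore, accession: str, residue_index: int
) -> list[SequenceFeatureRecord]:
    """All sequence features whose inclusive [start, end] interval
    contains ``residue_index``."""
    if residue_index < 1:
        raise ValueError("residue_index must be >= 1")
    return [
        feature
        for feature in store.sequence_features.get(accession, ())
        if feature.contains(residue_index)
    ]


# -- loading -------------------------------------------------------------


def _load_predictions(
    frame: pd.DataFrame, report: LoadReport
) -> dict[SubstitutionKey, PredictionProfile]:
    profiles: dict[SubstitutionKey, PredictionProfile] = {}
    raw_rows: dict[SubstitutionKey, tuple] = {}
    for i, row in frame.iterrows():
        try:
            key = _parse_key(row)
            entries = {}
            for alg in ALGORITHMS:
                entry = AlgorithmEntry(
                    raw=_float_cell(row, f"{alg}_raw"),
                    rescaled=_float_cell(row, f"{alg}_rescaled"),
                    call=_cell(row, f"{alg}_pred"),
                )
                if not entry.is_empty:
                    entries[alg] = entry
            conservation = {
                ind: _float_cell(row, ind) for ind in CONSERVATION_INDICATORS
            }
            ddg = _float_cell(row, "ddg")
            convention = _cell(row, "ddg_sign_convention")
            if ddg is not None and convention == "negative_destabilizing":
                ddg = -ddg  # normalize to positive = destabilizing
            ref_aa, alt_aa = key[2], key[3]
            profile = PredictionProfile(
                entries=entries,
                conservation=conservation,
                grantham=grantham_distance(ref_aa, alt_aa),
                ddg=ddg,
                stability_class_ingested=_cell(row, "stability_class"),
            )
        except (ValueError, KeyError) as exc:
            report.drop("predictions", int(i), str(exc))
            continue
        fingerprint = tuple(row.fillna("").astype(str))
        if key in profiles:
            if raw_rows[key] != fingerprint:
                raise StoreLoadError(
                    f"predictions: duplicate key {key} with conflicting values"
                )
            report.drop("predictions", int(i), "exact duplicate row")
            continue
        raw_rows[key] = fingerprint
        profiles[key] = profile
    return profiles


def _load_pathogenicity(
    frame: pd.DataFrame, report: LoadReport
) -> dict[SubstitutionKey, tuple[PathogenicityRecord, ...]]:
    records: dict[SubstitutionKey, list[PathogenicityRecord]] = {}
    for i, row in frame.iterrows():
        try:
            key = _parse_key(row)
            status = PathogenicityStatus(_cell(row, "status"))
            record = PathogenicityRecord(
                key=key,
                status=status,
                disease_name=_cell(row, "disease_name"),
                source=_cell(row, "source") or "other",
            )
        except (ValueError, KeyError) as exc:
            report.drop("pathogenicity", int(i), str(exc))
            continue
        bucket = records.setdefault(key, [])
        if record in bucket:
            report.drop("pathogenicity", int(i), "exact duplicate row")
            continue
        bucket.append(record)
    for key, bucket in records.items():
        if len({r.status for r in bucket}) > 1:
            report.warn(
                f"conflicting pathogenicity statuses for {key}: "
                f"{sorted(r.status.value for r in bucket)} "
                "(classifier will use the most severe)"
            )
    return {key: tuple(bucket) for key, bucket in records.items()}


def _split_list(value: Optional[str]) -> tuple[str, ...]:
    if value is None:
        return ()
    parts = [part.strip() for part in value.split("|") if part.strip()]
    return tuple(dict.fromkeys(parts))


def _load_gene_associations(
    frame: pd.DataFrame, report: LoadReport
) -> dict[str, GeneAssociationRecord]:
    out: dict[str, GeneAssociationRecord] = {}
    for i, row in frame.iterrows():
        try:
            gene = _cell(row, "gene")
            if gene is None:
                raise ValueError("missing gene symbol")
            record = GeneAssociationRecord(
                gene=gene,
                disease_assoc=_split_list(_cell(row, "disease_assoc")),
                trait_assoc=_split_list(_cell(row, "trait_assoc")),
                sources=_split_list(_cell(row, "sources")),
            )
        except ValueError as exc:
            report.drop("gene_associations", int(i), str(exc))
            continue
        if gene in out:
            if out[gene] != record:
                raise StoreLoadError(
                    f"gene_associations: duplicate gene {gene} with "
                    "conflicting values"
                )
            report.drop("gene_associations", int(i), "exact duplicate row")
            continue
        out[gene] = record
    return out


def _load_frequencies(
    frame: pd.DataFrame, report: LoadReport
) -> dict[SubstitutionKey, AlleleFrequencySet]:
    out: dict[SubstitutionKey, AlleleFrequencySet] = {}
    for i, row in frame.iterrows():
        try:
            key = _parse_key(row)

            def esp(column: str) -> Optional[float]:
                value = _float_cell(row, column)
                # ESP columns are published in percent
                return None if value is None else value / 100.0

            record = AlleleFrequencySet(
                maf_1kg_eur=_float_cell(row, "maf_1kg_eur"),
                maf_1kg_afr=_float_cell(row, "maf_1kg_afr"),
                maf_esp_ea=esp("maf_esp_ea"),
                maf_esp_aa=esp("maf_esp_aa"),
                maf_esp_all=esp("maf_esp_all"),
            )
        except ValueError as exc:
            report.drop("frequencies", int(i), str(exc))
            continue
        if key in out:
            if out[key] != record:
                raise StoreLoadError(
                    f"frequencies: duplicate key {key} with conflicting values"
                )
            report.drop("frequencies", int(i), "exact duplicate row")
            continue
        out[key] = record
    return out


def _load_sequence_features(
    frame: pd.DataFrame, report: LoadReport
) -> dict[str, tuple[SequenceFeatureRecord, ...]]:
    out: dict[str, list[SequenceFeatureRecord]] = {}
    for i, row in frame.iterrows():
        try:
            accession = _cell(row, "accession")
            feature_type = _cell(row, "feature_type")
            if accession is None or feature_type is None:
                raise ValueError("missing accession or feature_type")
            record = SequenceFeatureRecord(
                accession=accession,
                feature_type=feature_type,
                start=int(_cell(row, "start")),
                end=int(_cell(row, "end")),
                description=_cell(row, "description"),
            )
        except (TypeError, ValueError) as exc:
            report.drop("sequence_features", int(i), str(exc))
            continue
        out.setdefault(accession, []).append(record)
    return {accession: tuple(records) for accession, records in out.items()}


def _load_dbsnp(
    frame: pd.DataFrame, report: LoadReport
) -> tuple[tuple[str, Optional[str], Optional[int]], ...]:
    entries: dict[str, tuple[str, Optional[str], Optional[int]]] = {}
    for i, row in frame.iterrows():
        rsid = _cell(row, "rsid")
        if rsid is None:
            report.drop("dbsnp", int(i), "missing rsid")
            continue
        if rsid in entries:
            report.drop("dbsnp", int(i), "exact duplicate row")
            continue
        chrom, pos = _cell(row, "chrom"), _cell(row, "pos")
        entries[rsid] = (rsid, chrom, None if pos is None else int(pos))
    return tuple(entries.values())


def _load_isoform_map(
    frame: pd.DataFrame, report: LoadReport
) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    for i, row in frame.iterrows():
        gene = _cell(row, "gene")
        accession = _cell(row, "accession")
        transcript = _cell(row, "transcript")
        major = _cell(row, "major_isoform")
        if gene is None or accession is None or transcript is None:
            report.drop("isoform_map", int(i), "incomplete mapping row")
            continue
        if major not in ("1", "true", "True", "yes"):
            report.warn(
                f"isoform_map: non-major isoform row for gene {gene} "
                f"({transcript}) ignored"
            )
            report.drop("isoform_map", int(i), "non-major isoform")
            continue
        if gene in out and out[gene] != (accession, transcript):
            raise StoreLoadError(
                f"isoform_map: conflicting major-isoform rows for gene {gene}"
            )
        out[gene] = (accession, transcript)
    return out


def load_store(
    directory: str | Path, schema_version: str = "1"
) -> AnnotationStore:
    """Load a store from a directory of conventionally named TSV tables.

    Rows that fail type validation are dropped and listed in the load
    report; a missing mandatory column or a duplicate key with
    conflicting values is a hard error.
    """
    directory = Path(directory)
    frames = {
        table: _read_table(directory / filename, table)
        for table, filename in TABLE_FILES.items()
        if (directory / filename).exists() or table in ("predictions",)
    }
    return load_store_from_frames(frames, schema_version=schema_version)


def load_store_from_frames(
    frames: dict[str, pd.DataFrame], schema_version: str = "1"
) -> AnnotationStore:
    """Build a store directly from in-memory table frames (same schema
    and validation as :func:`load_store`)."""
    frames = dict(frames)
    report = LoadReport()
    # absent optional tables load as empty
    for table in TABLE_FILES:
        if table not in frames:
            frames[table] = pd.DataFrame(columns=MANDATORY_COLUMNS[table])
        for column in MANDATORY_COLUMNS[table]:
            if column not in frames[table].columns:
                raise StoreLoadError(
                    f"table {table} is missing mandatory column {column!r}"
                )

    profiles = _load_predictions(frames["predictions"], report)
    pathogenicity = _load_pathogenicity(frames["pathogenicity"], report)
    gene_assoc = _load_gene_associations(frames["gene_associations"], report)
    frequencies = _load_frequencies(frames["frequencies"], report)
    features = _load_sequence_features(frames["sequence_features"], report)
    dbsnp_entries = _load_dbsnp(frames["dbsnp"], report)
    isoform_map = _load_isoform_map(frames["isoform_map"], report)

    report.counts = {
        "predictions": len(profiles),
        "pathogenicity": sum(len(v) for v in pathogenicity.values()),
        "gene_associations": len(gene_assoc),
        "frequencies": len(frequencies),
        "sequence_features": sum(len(v) for v in features.values()),
        "dbsnp": len(dbsnp_entries),
        "isoform_map": len(isoform_map),
    }
    for table, frame in frames.items():
        loaded = report.counts.get(table, 0)
        dropped = sum(1 for t, _, _ in report.dropped if t == table)
        if loaded + dropped != len(frame):
            report.warn(
                f"{table}: loaded {loaded} + dropped {dropped} != "
                f"{len(frame)} input rows"
            )

    return AnnotationStore(
        profiles=profiles,
        pathogenicity=pathogenicity,
        frequencies=frequencies,
        gene_associations=gene_assoc,
        sequence_features=features,
        dbsnp_entries=dbsnp_entries,
        isoform_map=isoform_map,
        schema_version=schema_version,
        report=report,
    )


# -- writing (round-trip support) ----------------------------------------


def _fmt(value: object) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_store(store: AnnotationStore, directory: str | Path) -> None:
    """Write the store back to TSV tables (round-trips ``load_store``)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for key, profile in store.profiles.items():
        row: dict[str, str] = dict(
            zip(KEY_COLUMNS, (key[0], str(key[1]), key[2], key[3]))
        )
        for alg in ALGORITHMS:
            entry = profile.entry(alg)
            row[f"{alg}_raw"] = _fmt(entry.raw)
            row[f"{alg}_rescaled"] = _fmt(entry.rescaled)
            row[f"{alg}_pred"] = _fmt(entry.call)
        for ind in CONSERVATION_INDICATORS:
            row[ind] = _fmt(profile.conservation.get(ind))
        row["ddg"] = _fmt(profile.ddg)
        row["ddg_sign_convention"] = (
            MISSING_TOKEN if profile.ddg is None else "positive_destabilizing"
        )
        row["stability_class"] = _fmt(profile.stability_class_ingested)
        rows.append(row)
    columns = KEY_COLUMNS + [
        f"{alg}_{suffix}" for alg in ALGORITHMS for suffix in ("raw", "rescaled", "pred")
    ] + list(CONSERVATION_INDICATORS) + ["ddg", "ddg_sign_convention", "stability_class"]
    pd.DataFrame(rows, columns=columns).to_csv(
        directory / TABLE_FILES["predictions"], sep="\t", index=False
    )

    rows = [
        {
            "accession": key[0],
            "residue_index": str(key[1]),
            "ref_aa": key[2],
            "alt_aa": key[3],
            "status": record.status.value,
            "disease_name": _fmt(record.disease_name),
            "source": record.source,
        }
        for key, records in store.pathogenicity.items()
        for record in records
    ]
    pd.DataFrame(
        rows, columns=KEY_COLUMNS + ["status", "disease_name", "source"]
    ).to_csv(directory / TABLE_FILES["pathogenicity"], sep="\t", index=False)

    rows = [
        {
            "gene": record.gene,
            "disease_assoc": "|".join(record.disease_assoc) or MISSING_TOKEN,
            "trait_assoc": "|".join(record.trait_assoc) or MISSING_TOKEN,
            "sources": "|".join(record.sources) or MISSING_TOKEN,
        }
        for record in store.gene_associations.values()
    ]
    pd.DataFrame(
        rows, columns=["gene", "disease_assoc", "trait_assoc", "sources"]
    ).to_csv(directory / TABLE_FILES["gene_associations"], sep="\t", index=False)

    rows = [
        {
            "accession": key[0],
            "residue_index": str(key[1]),
            "ref_aa": key[2],
            "alt_aa": key[3],
            "maf_1kg_eur": _fmt(freq.maf_1kg_eur),
            "maf_1kg_afr": _fmt(freq.maf_1kg_afr),
            "maf_esp_ea": _fmt(
                None if freq.maf_esp_ea is None else freq.maf_esp_ea * 100.0
            ),
            "maf_esp_aa": _fmt(
                None if freq.maf_esp_aa is None else freq.maf_esp_aa * 100.0
            ),
            "maf_esp_all": _fmt(
                None if freq.maf_esp_all is None else freq.maf_esp_all * 100.0
            ),
        }
        for key, freq in store.frequencies.items()
    ]
    pd.DataFrame(
        rows,
        columns=KEY_COLUMNS
        + ["maf_1kg_eur", "maf_1kg_afr", "maf_esp_ea", "maf_esp_aa", "maf_esp_all"],
    ).to_csv(directory / TABLE_FILES["frequencies"], sep="\t", index=False)

    rows = [
        {
            "accession": feature.accession,
            "feature_type": feature.feature_type,
            "start": str(feature.start),
            "end": str(feature.end),
            "description": _fmt(feature.description),
        }
        for features in store.sequence_features.values()
        for feature in features
    ]
    pd.DataFrame(
        rows, columns=["accession", "feature_type", "start", "end", "description"]
    ).to_csv(directory / TABLE_FILES["sequence_features"], sep="\t", index=False)

    pd.DataFrame(
        [
            {"rsid": rsid, "chrom": _fmt(chrom), "pos": _fmt(pos)}
            for rsid, chrom, pos in sorted(store.dbsnp_entries, key=lambda e: e[0])
        ],
        columns=["rsid", "chrom", "pos"],
    ).to_csv(directory / TABLE_FILES["dbsnp"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "gene": gene,
                "accession": accession,
                "transcript": transcript,
                "major_isoform": "1",
            }
            for gene, (accession, transcript) in store.isoform_map.items()
        ],
        columns=["gene", "accession", "transcript", "major_isoform"],
    ).to_csv(directory / TABLE_FILES["isoform_map"], sep="\t", index=False)
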
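"""Cohort-level tables, distributions and statistics.

The central product is the category matrix: per-subject counts for each
of the 8 labels, a per-subject unique-variant total, and per-label cohort
totals.  Because 2A/3A/1/2B/3B are overlapping labels while 4/5/6 are
exclusive residual classes, every column obeys two reconciliation
identities::

    unique = |2A ∪ 3A| + n(4) + n(6)
    n(5)   = |2A ∪ 3A| - |2B ∪ 3B|

Headline statistics are exposed both as label sums (counting a variant
once per label it carries, the convention behind the printed per-category
totals) and as deduplicated variant counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classifier import LABELS, ClassifiedVariant
from .store import AnnotationStore, features_at
from .types import AlleleFrequencySet, ProteinVariant, SequenceFeatureRecord


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention behind printed integer
    percentages), unlike banker's rounding."""
    factor = 10**ndigits
    scaled = value * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


# -- category matrix -----------------------------------------------------


def category_matrix(results: Iterable[ClassifiedVariant]) -> pd.DataFrame:
    """Label-by-subject count matrix with a ``unique`` row (deduplicated
    variant counts per subject) and a ``total`` column (row sums)."""
    results = list(results)
    subjects = list(dict.fromkeys(r.subject_id for r in results))
    matrix = pd.DataFrame(0, index=list(LABELS) + ["unique"], columns=subjects)
    for record in results:
        for label in record.result.labels:
            matrix.loc[label, record.subject_id] += 1
        matrix.loc["unique", record.subject_id] += 1
    matrix["total"] = matrix.sum(axis=1)
    return matrix


def verify_reconciliation(results: Iterable[ClassifiedVariant]) -> bool:
    """Check the two column identities on a classified cohort."""
    results = list(results)
    by_subject: dict[str, list[ClassifiedVariant]] = {}
    for record in results:
        by_subject.setdefault(record.subject_id, []).append(record)
    for records in by_subject.values():
        n = {label: 0 for label in LABELS}
        union_a = union_b = 0
        for record in records:
            labels = record.result.labels
            for label in labels:
                n[label] += 1
            if labels & {"2A", "3A"}:
                union_a += 1
            if labels & {"2B", "3B"}:
                union_b += 1
        if len(records) != union_a + n["4"] + n["6"]:
            return False
        if n["5"] != union_a - union_b:
            return False
    return True


@dataclass(frozen=True)
class HeadlineStats:
    """Cohort headline numbers in both counting conventions."""

    n_variants: int
    n_subjects: int
    label_totals: dict[str, int]
    #: label-sum statistics (a 2B∩3B variant counts twice)
    top_priority_label_sum: int  # categories 1 + 2B + 3B
    mean_top_priority_per_genome: float
    combined_2b_3b: int
    ratio_2b3b_to_cat1: Optional[float]
    share_2b3b_of_2a3a_percent: float
    priority_space_label_sum: int  # categories 1 + 2B + 3B + 4
    #: deduplicated statistics
    top_priority_unique: int
    priority_space_unique: int

    def as_dict(self) -> dict[str, object]:
        from dataclasses import asdict

        return asdict(self)


def headline_stats(results: Iterable[ClassifiedVariant]) -> HeadlineStats:
    results = list(results)
    matrix = category_matrix(results)
    totals = {label: int(matrix.loc[label, "total"]) for label in LABELS}
    subjects = [c for c in matrix.columns if c != "total"]
    n_subjects = len(subjects)
    top_sum = totals["1"] + totals["2B"] + totals["3B"]
    combined = totals["2B"] + totals["3B"]
    assoc = totals["2A"] + totals["3A"]
    top_unique = sum(
        1 for r in results if r.result.labels & {"1", "2B", "3B"}
    )
    priority_unique = sum(
        1 for r in results if r.result.labels & {"1", "2B", "3B", "4"}
    )
    return HeadlineStats(
        n_variants=len(results),
        n_subjects=n_subjects,
        label_totals=totals,
        top_priority_label_sum=top_sum,
        mean_top_priority_per_genome=(
            top_sum / n_subjects if n_subjects else float("nan")
        ),
        combined_2b_3b=combined,
        ratio_2b3b_to_cat1=(combined / totals["1"] if totals["1"] else None),
        share_2b3b_of_2a3a_percent=(
            100.0 * combined / assoc if assoc else float("nan")
        ),
        priority_space_label_sum=top_sum + totals["4"],
        top_priority_unique=top_unique,
        priority_space_unique=priority_unique,
    )


# -- score distributions -------------------------------------------------


def prediction_count_histogram(
    consensus_counts: Iterable[int], conservation_counts: Iterable[int]
) -> tuple[pd.Series, pd.Series]:
    """Histograms of the 0-6 consensus and 0-3 conservation counts."""
    consensus = pd.Series(
        np.bincount(np.asarray(list(consensus_counts), dtype=int), minlength=7)[:7],
        index=range(7),
        name="n_deleterious_predictions",
    )
    conservation = pd.Series(
        np.bincount(np.asarray(list(conservation_counts), dtype=int), minlength=4)[:4],
        index=range(4),
        name="n_conserved_predictions",
    )
    return consensus, conservation


@dataclass(frozen=True)
class EcdfCurve:
    """Empirical CDF of one algorithm's re-scaled scores for one group."""

    group: str
    values: tuple[float, ...]
    fractions: tuple[float, ...]

    def at(self, x: float) -> float:
        """F(x) = fraction of scores <= x."""
        idx = np.searchsorted(self.values, x, side="right")
        return 0.0 if idx == 0 else self.fractions[idx - 1]


def score_ecdf(scores: Sequence[float], group: str = "") -> EcdfCurve:
    """Standard empirical CDF; tied scores share a single step."""
    if len(scores) == 0:
        raise ValueError("cannot build an ECDF from an empty score list")
    values = np.sort(np.asarray(scores, dtype=float))
    unique, counts = np.unique(values, return_counts=True)
    fractions = np.cumsum(counts) / len(values)
    return EcdfCurve(
        group=group,
        values=tuple(unique.tolist()),
        fractions=tuple(fractions.tolist()),
    )


# -- population bias -----------------------------------------------------


def population_bias_groups(
    snp_table: pd.DataFrame, cutoff_percent: float = 5.0
) -> dict[str, str]:
    """Group genes by the EA-vs-AA frequency bias of their SNPs.

    ``snp_table`` columns: ``gene``, ``maf_ea``, ``maf_aa`` (percent).
    A SNP is EA-biased when MAF_EA - MAF_AA > cutoff (strict), AA-biased
    when < -cutoff, otherwise unbiased.  A gene is ``EA_bias`` with >= 1
    EA-biased and no AA-biased SNP (symmetrically ``AA_bias``),
    ``EA_AA_bias`` with both, ``no_bias`` with neither.  SNPs missing
    both frequencies are skipped.
    """
    groups: dict[str, str] = {}
    flags: dict[str, set[str]] = {}
    for _, row in snp_table.iterrows():
        ea, aa = row.get("maf_ea"), row.get("maf_aa")
        if pd.isna(ea) and pd.isna(aa):
            continue
        ea = 0.0 if pd.isna(ea) else float(ea)
        aa = 0.0 if pd.isna(aa) else float(aa)
        diff = ea - aa
        bucket = flags.setdefault(str(row["gene"]), set())
        if diff > cutoff_percent:
            bucket.add("EA")
        elif diff < -cutoff_percent:
            bucket.add("AA")
    for gene, bucket in flags.items():
        if bucket == {"EA"}:
            groups[gene] = "EA_bias"
        elif bucket == {"AA"}:
            groups[gene] = "AA_bias"
        elif bucket == {"EA", "AA"}:
            groups[gene] = "EA_AA_bias"
        else:
            groups[gene] = "no_bias"
    return groups


# -- statistics ----------------------------------------------------------


def two_sample_ttest(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Student's pooled-variance two-sample t-test (two-tailed).

    Returns ``(t, p)`` with ``n1 + n2 - 2`` degrees of freedom.  Raises
    on samples smaller than 2 or zero pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample must have size >= 2")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


# -- sequence features ---------------------------------------------------


def relative_feature_position(
    residue_index: int, feature: SequenceFeatureRecord
) -> float:
    """Relative position of a residue inside a feature, in [0, 1].

    0 = feature N-terminus, 1 = C-terminus; a length-1 feature maps to 0.
    """
    if not feature.contains(residue_index):
        raise ValueError(
            f"residue {residue_index} outside feature "
            f"[{feature.start}, {feature.end}]"
        )
    span = feature.end - feature.start
    if span == 0:
        return 0.0
    return (residue_index - feature.start) / span


def feature_type_distribution(
    variants: Iterable[ProteinVariant], store: AnnotationStore
) -> pd.DataFrame:
    """Counts and percentages of variants per overlapped feature type.

    Percentages are over annotated variants only (those overlapping at
    least one feature); the fraction annotated is reported alongside.
    """
    variants = list(variants)
    per_type: dict[str, int] = {}
    n_annotated = 0
    for variant in variants:
        overlaps = features_at(store, variant.accession, variant.residue_index)
        if not overlaps:
            continue
        n_annotated += 1
        for feature_type in sorted({f.feature_type for f in overlaps}):
            per_type[feature_type] = per_type.get(feature_type, 0) + 1
    rows = [
        {
            "feature_type": feature_type,
            "n_variants": count,
            "percent_of_annotated": (
                round_half_away(100.0 * count / n_annotated)
                if n_annotated
                else float("nan")
            ),
        }
        for feature_type, count in sorted(
            per_type.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    frame = pd.DataFrame(
        rows, columns=["feature_type", "n_variants", "percent_of_annotated"]
    )
    frame.attrs["n_variants"] = len(variants)
    frame.attrs["n_annotated"] = n_annotated
    frame.attrs["fraction_annotated"] = (
        n_annotated / len(variants) if variants else float("nan")
    )
    return frame


# -- allele-frequency distributions by category --------------------------

MAF_GROUPS: tuple[str, ...] = ("2B_3B", "2A_3A", "5")


def _maf_groups(record: ClassifiedVariant) -> list[str]:
    """Groups a variant contributes to; 2A_3A spans every associated
    variant, so it overlaps both the deleterious and the neutral group."""
    labels = record.result.labels
    groups = []
    if labels & {"2B", "3B"}:
        groups.append("2B_3B")
    if labels & {"2A", "3A"}:
        groups.append("2A_3A")
    if "5" in labels:
        groups.append("5")
    return groups


def maf_distribution_by_category(
    results: Iterable[ClassifiedVariant], store: AnnotationStore
) -> dict[str, pd.DataFrame]:
    """Per-group ESP MAF vectors (percent) for the predicted-deleterious
    associated group (2B∪3B), remaining associated (2A/3A) and neutral
    associated (5) variants.  Variants without any frequency record are
    excluded from the group counts."""
    vectors: dict[str, list[dict[str, float]]] = {g: [] for g in MAF_GROUPS}
    for record in results:
        groups = _maf_groups(record)
        if not groups:
            continue
        freq = store.frequency(record.variant.key)
        if freq is None:
            continue
        present = {
            name: 100.0 * value
            for name, value in (
                ("maf_esp_ea", freq.maf_esp_ea),
                ("maf_esp_aa", freq.maf_esp_aa),
                ("maf_esp_all", freq.maf_esp_all),
            )
            if value is not None
        }
        if present:
            for group in groups:
                vectors[group].append(present)
    return {
        group: pd.DataFrame(rows, columns=["maf_esp_ea", "maf_esp_aa", "maf_esp_all"])
        for group, rows in vectors.items()
    }


def maf_group_summary(groups: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Median/quartile summary per group and population column."""
    rows = []
    for group, frame in groups.items():
        for column in frame.columns:
            series = frame[column].dropna()
            rows.append(
                {
                    "group": group,
                    "population": column,
                    "n": len(series),
                    "median": series.median() if len(series) else float("nan"),
                    "q1": series.quantile(0.25) if len(series) else float("nan"),
                    "q3": series.quantile(0.75) if len(series) else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["group", "population", "n", "median", "q1", "q3"])
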
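"""Synthetic annotation stores and cohorts with known ground truth.

The generator is plan-driven: a :class:`FixturePlan` states, per subject,
how many variants to plant in each exclusive class of the scheme
(deleterious-and-associated, deleterious-only, associated-but-neutral,
neither) together with the label overlaps, and the generator emits
annotation tables, a cohort variant table and a manifest recording every
variant's intended features and labels.  Prediction scores are always
generated consistently with the intended calls under default thresholds,
so classification recovers the plan exactly, not statistically.

Two packaged plans matter:

* :func:`table2_plan` — a 12-subject cohort whose planted label counts
  equal the published per-subject category matrix cell-for-cell (with
  the corresponding private-variant counts);
* :func:`table4_fixture` — the 10 worked-example substitutions (4
  documented disease-causal, 6 probable-pathogenic) with their printed
  frequencies, statuses, stability classes and site annotations.

Synthetic genes and accessions use a reserved SYN* namespace so fixture
rows can never join accidentally against real annotation data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .filters import CohortGenome
from .io import write_cohort_tsv
from .scores import ALGORITHMS, CONSERVATION_INDICATORS, CallThresholds
from .store import TABLE_FILES, AnnotationStore, load_store_from_frames
from .types import GenomicVariant, ProteinVariant, Zygosity

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Exclusive generation classes.  "bb" = deleterious in a gene with both
#: disease and trait associations (carries labels 2B and 3B).
CLASSES = (
    "bb",
    "b2_only",
    "b3_only",
    "ab_neutral",
    "a2_only",
    "a3_only",
    "cat4",
    "cat6",
    "private",
)


@dataclass(frozen=True)
class SubjectPlan:
    """Planted per-class variant counts for one genome."""

    subject_id: str
    ethnicity: str = "Caucasian"
    sex: str = "F"
    n_cat1: int = 0  # variants additionally documented disease-causing
    n_bb: int = 0  # deleterious, disease+trait gene (2B and 3B)
    n_b2_only: int = 0  # deleterious, disease gene only (2B)
    n_b3_only: int = 0  # deleterious, trait gene only (3B)
    n_ab_neutral: int = 0  # neutral, disease+trait gene (2A and 3A)
    n_a2_only: int = 0  # neutral, disease gene only
    n_a3_only: int = 0  # neutral, trait gene only
    n_cat4: int = 0  # deleterious, no association
    n_cat6: int = 0  # neutral, no association
    n_private: int = 0  # absent from the dbSNP snapshot

    def __post_init__(self) -> None:
        for name in (
            "n_cat1",
            "n_bb",
            "n_b2_only",
            "n_b3_only",
            "n_ab_neutral",
            "n_a2_only",
            "n_a3_only",
            "n_cat4",
            "n_cat6",
            "n_private",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cat1 > self.disease_gene_slots:
            raise ValueError(
                f"subject {self.subject_id}: n_cat1={self.n_cat1} exceeds the "
                f"{self.disease_gene_slots} disease-gene variants available"
            )

    @property
    def disease_gene_slots(self) -> int:
        return self.n_bb + self.n_b2_only + self.n_ab_neutral + self.n_a2_only

    @property
    def n_known(self) -> int:
        return (
            self.n_bb
            + self.n_b2_only
            + self.n_b3_only
            + self.n_ab_neutral
            + self.n_a2_only
            + self.n_a3_only
            + self.n_cat4
            + self.n_cat6
        )

    def expected_label_counts(self) -> dict[str, int]:
        """Label counts this plan implies under the classifier."""
        return {
            "1": self.n_cat1,
            "2A": self.n_bb + self.n_b2_only + self.n_ab_neutral + self.n_a2_only,
            "2B": self.n_bb + self.n_b2_only,
            "3A": self.n_bb + self.n_b3_only + self.n_ab_neutral + self.n_a3_only,
            "3B": self.n_bb + self.n_b3_only,
            "4": self.n_cat4,
            "5": self.n_ab_neutral + self.n_a2_only + self.n_a3_only,
            "6": self.n_cat6,
        }


@dataclass(frozen=True)
class FixturePlan:
    """A full cohort plan plus the score- and frequency-generation rules."""

    seed: int
    subjects: tuple[SubjectPlan, ...]
    #: Beta(a, b) shape parameters for matched-population MAFs, scaled
    #: into [0, maf_cap); the deleterious-associated classes draw from
    #: the lower-mean pair to mirror the observed frequency shift.
    maf_beta_deleterious: tuple[float, float] = (0.6, 16.0)
    maf_beta_neutral: tuple[float, float] = (2.0, 10.0)
    maf_cap: float = 0.0999

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique within a plan")


@dataclass
class FixtureBundle:
    """Generated tables, cohort and ground-truth manifest."""

    frames: dict[str, pd.DataFrame]
    cohort: list[CohortGenome]
    manifest: pd.DataFrame

    def store(self) -> AnnotationStore:
        return load_store_from_frames(self.frames)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for table, filename in TABLE_FILES.items():
            if table in self.frames:
                self.frames[table].to_csv(
                    directory / filename, sep="\t", index=False
                )
        write_cohort_tsv(self.cohort, directory / "cohort.tsv")
        self.manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)


# -- score generation ----------------------------------------------------

_DELETERIOUS_ENTRY = {
    "sift": ("{:.4f}", "D"),
    "lrt": ("{:.4f}", "D"),
    "mutationassessor": ("{:.3f}", "H"),
    "polyphen2_humdiv": ("{:.3f}", "D"),
    "polyphen2_humvar": ("{:.3f}", "D"),
    "mutationtaster": ("{:.3f}", "D"),
}


def _deleterious_raw(algorithm: str, rng: np.random.Generator) -> float:
    """A raw score safely past the damaging cutoff."""
    if algorithm == "sift":
        return float(rng.uniform(0.0, 0.04))  # rescaled >= 0.96
    if algorithm == "lrt":
        return float(rng.uniform(0.9992, 1.0))
    if algorithm == "mutationassessor":
        return float(rng.uniform(3.6, 5.5))
    return float(rng.uniform(0.95, 1.0))  # polyphen2 / mutationtaster


def _tolerated_raw(algorithm: str, rng: np.random.Generator) -> float:
    if algorithm == "sift":
        return float(rng.uniform(0.2, 1.0))
    if algorithm == "lrt":
        return float(rng.uniform(0.0, 0.9))
    if algorithm == "mutationassessor":
        return float(rng.uniform(-2.0, 3.0))
    return float(rng.uniform(0.0, 0.4))


_TOLERATED_CALL = {
    "sift": "T",
    "lrt": "N",
    "mutationassessor": "L",
    "polyphen2_humdiv": "B",
    "polyphen2_humvar": "B",
    "mutationtaster": "N",
}

_CONSERVATION_HIGH = {"gerp_rs": (2.5, 6.0), "phylop": (2.0, 9.0), "siphy": (13.0, 20.0)}
_CONSERVATION_LOW = {"gerp_rs": (-3.0, 1.5), "phylop": (-2.0, 1.0), "siphy": (0.0, 10.0)}


def _prediction_row(
    key: tuple[str, int, str, str],
    consensus_target: int,
    conservation_target: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    from .scores import rescale_score

    accession, residue_index, ref_aa, alt_aa = key
    row: dict[str, str] = {
        "accession": accession,
        "residue_index": str(residue_index),
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
    }
    damaging = set(
        rng.choice(len(ALGORITHMS), size=consensus_target, replace=False).tolist()
    )
    for i, algorithm in enumerate(ALGORITHMS):
        fmt, call = _DELETERIOUS_ENTRY[algorithm]
        if i in damaging:
            raw = _deleterious_raw(algorithm, rng)
            pred = call
        else:
            raw = _tolerated_raw(algorithm, rng)
            pred = _TOLERATED_CALL[algorithm]
        row[f"{algorithm}_raw"] = fmt.format(raw)
        row[f"{algorithm}_rescaled"] = "{:.4f}".format(
            rescale_score(algorithm, raw)
        )
        row[f"{algorithm}_pred"] = pred
    conserved = set(
        rng.choice(
            len(CONSERVATION_INDICATORS), size=conservation_target, replace=False
        ).tolist()
    )
    for i, indicator in enumerate(CONSERVATION_INDICATORS):
        lo, hi = (
            _CONSERVATION_HIGH[indicator]
            if i in conserved
            else _CONSERVATION_LOW[indicator]
        )
        row[indicator] = "{:.2f}".format(rng.uniform(lo, hi))
    row["ddg"] = "{:.2f}".format(rng.normal(0.0, 1.2))
    row["ddg_sign_convention"] = "positive_destabilizing"
    row["stability_class"] = "."
    return row


# -- generation ----------------------------------------------------------

_CLASS_FEATURES = {
    # class -> (deleterious, disease_gene, trait_gene)
    "bb": (True, True, True),
    "b2_only": (True, True, False),
    "b3_only": (True, False, True),
    "ab_neutral": (False, True, True),
    "a2_only": (False, True, False),
    "a3_only": (False, False, True),
    "cat4": (True, False, False),
    "cat6": (False, False, False),
    "private": (False, False, False),
}

#: Order in which documented disease-causing status is assigned to a
#: subject's disease-gene variants.
_CAT1_PREFERENCE = ("bb", "b2_only", "ab_neutral", "a2_only")


def generate(plan: FixturePlan) -> FixtureBundle:
    """Generate annotation tables, cohort and manifest from a plan.

    Deterministic for a given plan (byte-identical tables when written
    twice with the same seed).
    """
    rng = np.random.default_rng(plan.seed)
    counter = itertools.count(1)

    predictions: list[dict[str, str]] = []
    pathogenicity: list[dict[str, str]] = []
    gene_assoc: list[dict[str, str]] = []
    frequencies: list[dict[str, str]] = []
    features: list[dict[str, str]] = []
    dbsnp: list[dict[str, str]] = []
    isoform: list[dict[str, str]] = []
    manifest_rows: list[dict[str, object]] = []
    cohort: list[CohortGenome] = []

    for subject in plan.subjects:
        genome = CohortGenome(
            subject_id=subject.subject_id,
            ethnicity=subject.ethnicity,
            sex=subject.sex,
        )
        cohort.append(genome)
        class_counts = [
            ("bb", subject.n_bb),
            ("b2_only", subject.n_b2_only),
            ("b3_only", subject.n_b3_only),
            ("ab_neutral", subject.n_ab_neutral),
            ("a2_only", subject.n_a2_only),
            ("a3_only", subject.n_a3_only),
            ("cat4", subject.n_cat4),
            ("cat6", subject.n_cat6),
            ("private", subject.n_private),
        ]
        cat1_remaining = subject.n_cat1
        for class_name, count in class_counts:
            for _ in range(count):
                idx = next(counter)
                deleterious, disease_gene, trait_gene = _CLASS_FEATURES[class_name]
                is_private = class_name == "private"
                # greedy placement of documented-causal marks on the
                # subject's disease-gene variants (class order already
                # matches the preference order)
                disease_causing = False
                if cat1_remaining > 0 and class_name in _CAT1_PREFERENCE:
                    disease_causing = True
                    cat1_remaining -= 1

                gene = f"SYNG{idx:05d}"
                accession = f"SYN{idx:05d}"
                transcript = f"SYNT{idx:05d}"
                chrom = str(1 + (idx % 22))
                pos = 10_000 + idx * 37
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                residue_index = int(rng.integers(2, 500))
                ref_aa, alt_aa = (
                    AA[i] for i in rng.choice(len(AA), size=2, replace=False)
                )
                rsid = None if is_private else f"rs77{idx:06d}"
                key = (accession, residue_index, ref_aa, alt_aa)

                consensus_target = (
                    int(rng.integers(3, 7)) if deleterious else int(rng.integers(0, 3))
                )
                conservation_target = int(rng.integers(0, 4))
                predictions.append(
                    _prediction_row(key, consensus_target, conservation_target, rng)
                )

                beta = (
                    plan.maf_beta_deleterious
                    if deleterious and (disease_gene or trait_gene)
                    else plan.maf_beta_neutral
                )
                maf = float(rng.beta(*beta) * plan.maf_cap)
                esp_scale = float(rng.uniform(0.5, 1.5))
                frequencies.append(
                    {
                        "accession": accession,
                        "residue_index": str(residue_index),
                        "ref_aa": ref_aa,
                        "alt_aa": alt_aa,
                        "maf_1kg_eur": "{:.5f}".format(maf),
                        "maf_1kg_afr": "{:.5f}".format(
                            min(maf * float(rng.uniform(0.5, 1.5)), plan.maf_cap)
                        ),
                        "maf_esp_ea": "{:.3f}".format(100 * maf * esp_scale),
                        "maf_esp_aa": "{:.3f}".format(
                            100 * maf * float(rng.uniform(0.5, 1.5))
                        ),
                        "maf_esp_all": "{:.3f}".format(100 * maf),
                    }
                )

                if disease_causing:
                    pathogenicity.append(
                        {
                            "accession": accession,
                            "residue_index": str(residue_index),
                            "ref_aa": ref_aa,
                            "alt_aa": alt_aa,
                            "status": "disease_causing",
                            "disease_name": f"synthetic disorder {idx}",
                            "source": "MSV3d",
                        }
                    )

                gene_assoc.append(
                    {
                        "gene": gene,
                        "disease_assoc": (
                            f"synthetic disease of {gene}" if disease_gene else "."
                        ),
                        "trait_assoc": (
                            f"synthetic trait of {gene}" if trait_gene else "."
                        ),
                        "sources": "synthetic",
                    }
                )
                if rng.uniform() < 0.6:
                    start = max(1, residue_index - int(rng.integers(0, 20)))
                    end = residue_index + int(rng.integers(0, 20))
                    feature_type = str(
                        rng.choice(["DOMAIN", "TRANSMEM", "REPEAT", "REGION"])
                    )
                    features.append(
                        {
                            "accession": accession,
                            "feature_type": feature_type,
                            "start": str(start),
                            "end": str(end),
                            "description": ".",
                        }
                    )
                if rsid is not None:
                    dbsnp.append({"rsid": rsid, "chrom": chrom, "pos": str(pos)})
                isoform.append(
                    {
                        "gene": gene,
                        "accession": accession,
                        "transcript": transcript,
                        "major_isoform": "1",
                    }
                )

                genome.variants.append(
                    ProteinVariant(
                        variant=GenomicVariant(
                            chrom=chrom,
                            pos=pos,
                            ref=str(ref),
                            alt=str(alt),
                            rsid=rsid,
                            zygosity=Zygosity.HOM_ALT,
                            qual=50.0,
                        ),
                        gene=gene,
                        accession=accession,
                        transcript=transcript,
                        residue_index=residue_index,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                    )
                )
                manifest_rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "class": class_name,
                        "gene": gene,
                        "accession": accession,
                        "residue_index": residue_index,
                        "ref_aa": ref_aa,
                        "alt_aa": alt_aa,
                        "rsid": rsid or ".",
                        "chrom": chrom,
                        "pos": pos,
                        "private": is_private,
                        "disease_causing": disease_causing,
                        "deleterious": deleterious,
                        "in_disease_gene": disease_gene,
                        "in_trait_gene": trait_gene,
                        "consensus_count": consensus_target,
                        "conservation_count": conservation_target,
                        "labels": "|".join(
                            sorted(
                                _expected_labels(
                                    disease_causing,
                                    deleterious,
                                    disease_gene,
                                    trait_gene,
                                )
                            )
                        ),
                    }
                )
        if cat1_remaining:
            raise ValueError(
                f"subject {subject.subject_id}: could not place "
                f"{cat1_remaining} disease-causing mark(s); plan infeasible"
            )

    frames = {
        "predictions": pd.DataFrame(predictions),
        "pathogenicity": pd.DataFrame(
            pathogenicity,
            columns=[
                "accession",
                "residue_index",
                "ref_aa",
                "alt_aa",
                "status",
                "disease_name",
                "source",
            ],
        ),
        "gene_associations": pd.DataFrame(
            gene_assoc, columns=["gene", "disease_assoc", "trait_assoc", "sources"]
        ),
        "frequencies": pd.DataFrame(frequencies),
        "sequence_features": pd.DataFrame(
            features,
            columns=["accession", "feature_type", "start", "end", "description"],
        ),
        "dbsnp": pd.DataFrame(dbsnp, columns=["rsid", "chrom", "pos"]),
        "isoform_map": pd.DataFrame(
            isoform, columns=["gene", "accession", "transcript", "major_isoform"]
        ),
    }
    manifest = pd.DataFrame(manifest_rows)
    return FixtureBundle(frames=frames, cohort=cohort, manifest=manifest)


def _expected_labels(
    disease_causing: bool, deleterious: bool, disease_gene: bool, trait_gene: bool
) -> set[str]:
    labels: set[str] = set()
    if disease_causing:
        labels.add("1")
    if disease_gene:
        labels.add("2A")
        if deleterious:
            labels.add("2B")
    if trait_gene:
        labels.add("3A")
        if deleterious:
            labels.add("3B")
    if deleterious and not disease_gene and not trait_gene:
        labels.add("4")
    if (disease_gene or trait_gene) and not deleterious:
        labels.add("5")
    if not labels:
        labels.add("6")
    return labels


# -- packaged plans ------------------------------------------------------

_T2_ETHNICITY = ["African"] * 4 + ["Caucasian"] * 8
_T2_SEX = ["F"] * 8 + ["M"] * 4
_T2_CAT1 = [1, 0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 0]
_T2_2A = [8, 7, 6, 5, 6, 5, 11, 7, 12, 7, 10, 9]
_T2_2B = [1, 0, 0, 0, 2, 2, 4, 1, 2, 0, 2, 0]
_T2_3A = [9, 24, 17, 7, 6, 10, 9, 10, 5, 13, 16, 10]
_T2_3B = [1, 5, 0, 0, 1, 1, 3, 4, 2, 2, 0, 2]
_T2_CAT4 = [5, 5, 8, 6, 0, 5, 3, 7, 4, 6, 5, 4]
_T2_CAT5 = [14, 21, 20, 10, 8, 12, 9, 11, 13, 18, 20, 14]
_T2_CAT6 = [68, 40, 49, 42, 46, 32, 33, 33, 40, 56, 45, 55]
_T2_UNIQUE = [88, 71, 77, 58, 57, 52, 50, 55, 60, 82, 72, 75]
_T1_PRIVATE = [2, 3, 3, 1, 2, 0, 4, 0, 2, 2, 5, 5]


def table2_plan(seed: int = 1) -> FixturePlan:
    """The packaged 12-genome plan replicating the published category
    matrix cell-for-cell, with the published private-variant counts.

    The label overlaps (2A∩3A and 2B∩3B per subject) are the unique
    solution of the reconciliation identities
    ``unique = |2A∪3A| + n4 + n6`` and ``n5 = |2A∪3A| - |2B∪3B|``.
    """
    subjects = []
    for i in range(12):
        union_a = _T2_UNIQUE[i] - _T2_CAT4[i] - _T2_CAT6[i]
        union_b = union_a - _T2_CAT5[i]
        bb = _T2_2B[i] + _T2_3B[i] - union_b
        inter_a = _T2_2A[i] + _T2_3A[i] - union_a
        ab_neutral = inter_a - bb
        subjects.append(
            SubjectPlan(
                subject_id=str(i + 1),
                ethnicity=_T2_ETHNICITY[i],
                sex=_T2_SEX[i],
                n_cat1=_T2_CAT1[i],
                n_bb=bb,
                n_b2_only=_T2_2B[i] - bb,
                n_b3_only=_T2_3B[i] - bb,
                n_ab_neutral=ab_neutral,
                n_a2_only=_T2_2A[i] - _T2_2B[i] - ab_neutral,
                n_a3_only=_T2_3A[i] - _T2_3B[i] - ab_neutral,
                n_cat4=_T2_CAT4[i],
                n_cat6=_T2_CAT6[i],
                n_private=_T1_PRIVATE[i],
            )
        )
    return FixturePlan(seed=seed, subjects=tuple(subjects))


def random_plan(seed: int, n_subjects: int = 4, scale: int = 12) -> FixturePlan:
    """A random feasible plan (for property tests)."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        n_bb = int(rng.integers(0, scale // 4 + 1))
        n_b2 = int(rng.integers(0, scale // 2 + 1))
        n_ab = int(rng.integers(0, scale // 3 + 1))
        n_a2 = int(rng.integers(0, scale + 1))
        cat1_cap = n_bb + n_b2 + n_ab + n_a2
        subjects.append(
            SubjectPlan(
                subject_id=f"R{i + 1}",
                ethnicity=str(rng.choice(["African", "Caucasian"])),
                sex=str(rng.choice(["F", "M"])),
                n_cat1=int(rng.integers(0, min(3, cat1_cap) + 1)),
                n_bb=n_bb,
                n_b2_only=n_b2,
                n_b3_only=int(rng.integers(0, scale // 2 + 1)),
                n_ab_neutral=n_ab,
                n_a2_only=n_a2,
                n_a3_only=int(rng.integers(0, scale + 1)),
                n_cat4=int(rng.integers(0, scale + 1)),
                n_cat6=int(rng.integers(0, 3 * scale + 1)),
                n_private=int(rng.integers(0, 4)),
            )
        )
    return FixturePlan(seed=int(rng.integers(0, 2**31 - 1)), subjects=tuple(subjects))


# -- the worked-example table -------------------------------------------

_TABLE4_ROWS = [
    # gene, accession, chrom, pos, ref, alt, aa_change, rsid,
    # esp (EA, AA, All) in percent, status, disease, stability_class,
    # feature (type, start, end, description), del_count, con_count, ddg
    ("ATP6V0A4", "Q9HBG4", "7", 138417791, "A", "G", ("M", 580, "T"),
     "rs3807153", (4.8, 18.5, 9.4), "disease_causing",
     "Distal renal tubular acidosis (dRTA) with preserved hearing",
     "Neutral", ("TRANSMEM", 565, 585, None), 2, 3, None),
    ("MTMR2", "Q13614", "11", 95569448, "T", "C", ("N", 545, "S"),
     "rs558018", (0.02, 3.9, 1.3), "disease_causing",
     "Charcot-Marie-Tooth disease type 4B1 (CMT4B1)",
     "Decrease", ("DOMAIN", 420, 586, None), 2, 3, 0.36),
    ("APOE", "P02649", "19", 45412079, "C", "T", ("R", 176, "C"),
     "rs7412", (5.6, 8.7, 6.6), "disease_causing",
     "Lipoprotein glomerulopathy (LPG)",
     "Decrease", ("REPEAT", 168, 189, None), 5, 3, -0.46),
    ("BMP15", "O95972", "X", 50658966, "G", "A", ("A", 180, "T"),
     "rs104894767", (1.4, 0.3, 1.0), "disease_causing",
     "Premature ovarian failure type 4 (POF4)",
     "Neutral", ("PROPEP", 26, 267, None), 0, 1, None),
    ("FRZB", "Q92765", "2", 183699584, "G", "C", ("R", 324, "G"),
     "rs7775", (8.8, 28.4, 15.4), "probable",
     "Osteoarthritis type 1 (OS1)", "Neutral", None, 1, 3, None),
    ("HABP2", "Q14520", "10", 115348046, "G", "A", ("G", 534, "E"),
     "rs7080536", (3.9, 0.7, 2.8), "probable", None,
     "Decrease", ("DOMAIN", 373, 560, None), 5, 3, None),
    ("HNF1A", "P20823", "12", 121416650, "A", "C", ("I", 27, "L"),
     "rs1169288", (33.5, 12.1, 26.2), "probable",
     "Insulin-dependent diabetes mellitus type 20 (IDDM20)",
     "Neutral", ("REGION", 1, 32, "Dimerization"), 1, 3, None),
    ("XYLT1", "Q86Y38", "16", 17564311, "C", "A", ("A", 115, "S"),
     "rs61758388", (None, None, 1.7), "probable", None,
     "Neutral", ("TOPO_DOM", 30, 959, None), 0, 3, None),
    ("CYP2A6", "P11509", "19", 41354533, "A", "T", ("L", 160, "H"),
     "rs1801272", (2.5, 0.5, 1.8), "probable", None,
     "Decrease", None, 1, 3, None),
    ("ADA", "P00813", "20", 43255220, "T", "C", ("K", 80, "R"),
     "rs11555566", (6.3, 6.8, 6.5), "probable",
     "Severe combined immunodeficiency autosomal recessive T-cell-negative/"
     "B-cell-negative/NK-cell-negative due to adenosine deaminase deficiency "
     "(ADASCID)", "Decrease", None, 1, 3, None),
]


def table4_fixture() -> FixtureBundle:
    """Annotation tables and a carrier pseudo-genome for the 10
    worked-example variants: 4 documented disease-causal and 6
    probable-pathogenic substitutions, with their printed allele
    frequencies, stability classes and site annotations.

    Score rows are planted so each substitution reaches exactly its
    printed deleterious and conservation counts under the default
    thresholds.  The APOE gene carries both disease and trait
    associations (the variant is the scheme's 1/2B/3B showcase); the
    other genes carry a disease association only.
    """
    rng = np.random.default_rng(20130101)  # fixed: tables are constants
    predictions, pathogenicity, gene_assoc = [], [], []
    frequencies, features, dbsnp, isoform = [], [], [], []
    genome = CohortGenome(subject_id="T4", ethnicity="Caucasian", sex="F")

    for row in _TABLE4_ROWS:
        (gene, accession, chrom, pos, ref, alt, aa, rsid, esp, status,
         disease, stability, feature, del_count, con_count, ddg) = row
        ref_aa, residue_index, alt_aa = aa
        key = (accession, residue_index, ref_aa, alt_aa)
        prow = _prediction_row(key, del_count, con_count, rng)
        prow["ddg"] = "." if ddg is None else "{:.2f}".format(ddg)
        prow["stability_class"] = stability
        predictions.append(prow)
        pathogenicity.append(
            {
                "accession": accession,
                "residue_index": str(residue_index),
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "status": status,
                "disease_name": disease or ".",
                "source": "MSV3d",
            }
        )
        gene_assoc.append(
            {
                "gene": gene,
                "disease_assoc": f"disease association of {gene}",
                "trait_assoc": (
                    "lipid levels|Alzheimer disease risk" if gene == "APOE" else "."
                ),
                "sources": "OMIM|GWAS",
            }
        )
        ea, aa_freq, all_freq = esp
        frequencies.append(
            {
                "accession": accession,
                "residue_index": str(residue_index),
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "maf_1kg_eur": "{:.4f}".format(all_freq / 100.0),
                "maf_1kg_afr": (
                    "." if aa_freq is None else "{:.4f}".format(aa_freq / 100.0)
                ),
                "maf_esp_ea": "." if ea is None else "{:.2f}".format(ea),
                "maf_esp_aa": "." if aa_freq is None else "{:.2f}".format(aa_freq),
                "maf_esp_all": "{:.2f}".format(all_freq),
            }
        )
        if feature is not None:
            feature_type, start, end, description = feature
            features.append(
                {
                    "accession": accession,
                    "feature_type": feature_type,
                    "start": str(start),
                    "end": str(end),
                    "description": description or ".",
                }
            )
        dbsnp.append({"rsid": rsid, "chrom": chrom, "pos": str(pos)})
        transcript = f"TX_{gene}"
        isoform.append(
            {
                "gene": gene,
                "accession": accession,
                "transcript": transcript,
                "major_isoform": "1",
            }
        )
        genome.variants.append(
            ProteinVariant(
                variant=GenomicVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    rsid=rsid,
                    zygosity=Zygosity.HOM_ALT,
                    qual=50.0,
                ),
                gene=gene,
                accession=accession,
                transcript=transcript,
                residue_index=residue_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )

    frames = {
        "predictions": pd.DataFrame(predictions),
        "pathogenicity": pd.DataFrame(pathogenicity),
        "gene_associations": pd.DataFrame(gene_assoc),
        "frequencies": pd.DataFrame(frequencies),
        "sequence_features": pd.DataFrame(
            features,
            columns=["accession", "feature_type", "start", "end", "description"],
        ),
        "dbsnp": pd.DataFrame(dbsnp),
        "isoform_map": pd.DataFrame(isoform),
    }
    manifest = pd.DataFrame(
        [
            {
                "gene": row[0],
                "accession": row[1],
                "residue_index": row[6][1],
                "ref_aa": row[6][0],
                "alt_aa": row[6][2],
                "status": row[9],
                "stability_class": row[11],
                "del_count": row[13],
                "con_count": row[14],
            }
            for row in _TABLE4_ROWS
        ]
    )
    return FixtureBundle(frames=frames, cohort=[genome], manifest=manifest)
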
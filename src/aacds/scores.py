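"""Per-algorithm deleteriousness calls, consensus and conservation counts,
and the protein-stability class.

Six prediction programs feed the consensus: SIFT, LRT, MutationAssessor,
PolyPhen2 (HumDiv and HumVar) and MutationTaster.  Their raw scores are
re-scaled to [0, 1] with 1 = most deleterious (SIFT is orientation-flipped;
MutationAssessor is min-max scaled over its published range; the others
already live on [0, 1]).  A substitution is "deleterious" in the scheme
when at least three of the six programs call it damaging.

Three evolutionary-constraint indicators (GERP++ RS, phyloP, SiPhy) give a
separate 0-3 conservation count.  Neither the conservation count nor the
Grantham distance enters the category assignment; they are reported for
comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

ALGORITHMS: tuple[str, ...] = (
    "sift",
    "lrt",
    "mutationassessor",
    "polyphen2_humdiv",
    "polyphen2_humvar",
    "mutationtaster",
)

CONSERVATION_INDICATORS: tuple[str, ...] = ("gerp_rs", "phylop", "siphy")

#: Published raw-score bounds per algorithm and whether the raw scale must
#: be orientation-flipped so that 1 = most deleterious after re-scaling.
#: MutationAssessor bounds follow the dbNSFP documentation for its
#: functional-impact scale; the remaining programs emit probabilities.
SCORE_BOUNDS: dict[str, tuple[float, float, bool]] = {
    "sift": (0.0, 1.0, True),
    "lrt": (0.0, 1.0, False),
    "mutationassessor": (-5.545, 5.975, False),
    "polyphen2_humdiv": (0.0, 1.0, False),
    "polyphen2_humvar": (0.0, 1.0, False),
    "mutationtaster": (0.0, 1.0, False),
}

#: Categorical labels treated as a damaging call, per source convention:
#: SIFT D=damaging; LRT D=deleterious; MutationAssessor H=high impact;
#: PolyPhen2 D=probably damaging, P=possibly damaging; MutationTaster
#: A=disease causing automatic, D=disease causing.
DELETERIOUS_LABELS: dict[str, frozenset[str]] = {
    "sift": frozenset({"D"}),
    "lrt": frozenset({"D"}),
    "mutationassessor": frozenset({"H"}),
    "polyphen2_humdiv": frozenset({"D", "P"}),
    "polyphen2_humvar": frozenset({"D", "P"}),
    "mutationtaster": frozenset({"A", "D"}),
}


class Call(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


@dataclass(frozen=True)
class AlgorithmEntry:
    """One algorithm's view of one substitution; any field may be absent."""

    raw: Optional[float] = None
    rescaled: Optional[float] = None
    call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rescaled is not None and not 0.0 <= self.rescaled <= 1.0:
            raise ValueError(f"rescaled score {self.rescaled} outside [0, 1]")

    @property
    def is_empty(self) -> bool:
        return self.raw is None and self.rescaled is None and self.call is None


@dataclass(frozen=True)
class PredictionProfile:
    """Scores for one substitution: 6 predictors + 3 conservation
    indicators + Grantham distance + stability change."""

    entries: dict[str, AlgorithmEntry] = field(default_factory=dict)
    conservation: dict[str, Optional[float]] = field(default_factory=dict)
    grantham: Optional[int] = None
    ddg: Optional[float] = None
    stability_class_ingested: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.entries) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms in profile: {sorted(unknown)}")
        unknown = set(self.conservation) - set(CONSERVATION_INDICATORS)
        if unknown:
            raise ValueError(f"unknown conservation indicators: {sorted(unknown)}")
        if self.grantham is not None and self.grantham < 0:
            raise ValueError("grantham distance must be non-negative")

    def entry(self, algorithm: str) -> AlgorithmEntry:
        return self.entries.get(algorithm, AlgorithmEntry())


@dataclass(frozen=True)
class CallThresholds:
    """Damaging cutoffs, all overridable from configuration.

    The two stated cutoffs are MutationAssessor raw > 3.5 (strict) and
    LRT 0.999 on the re-scaled scale.  The remaining deleteriousness and
    all conservation cutoffs are package defaults, echoed into every
    report header for provenance.
    """

    sift_rescaled: float = 0.95  # raw SIFT <= 0.05
    lrt_rescaled: float = 0.999
    mutationassessor_raw: float = 3.5  # strict >
    polyphen2_humdiv_rescaled: float = 0.5
    polyphen2_humvar_rescaled: float = 0.5
    mutationtaster_rescaled: float = 0.5
    gerp_rs: float = 2.0
    phylop: float = 1.6
    siphy: float = 12.0
    #: When True a categorical source label decides the call where present;
    #: otherwise calls always come from score-vs-cutoff.
    prefer_categorical: bool = True

    def rescaled_cutoff(self, algorithm: str) -> float:
        return {
            "sift": self.sift_rescaled,
            "lrt": self.lrt_rescaled,
            "polyphen2_humdiv": self.polyphen2_humdiv_rescaled,
            "polyphen2_humvar": self.polyphen2_humvar_rescaled,
            "mutationtaster": self.mutationtaster_rescaled,
        }[algorithm]

    def conservation_cutoff(self, indicator: str) -> float:
        return {
            "gerp_rs": self.gerp_rs,
            "phylop": self.phylop,
            "siphy": self.siphy,
        }[indicator]

    def as_dict(self) -> dict[str, object]:
        from dataclasses import asdict

        return asdict(self)

    def replace(self, **kwargs: object) -> "CallThresholds":
        return replace(self, **kwargs)


def rescale_score(algorithm: str, raw: float) -> float:
    """Map a raw score onto [0, 1] with 1 = most deleterious.

    SIFT is flipped (1 - raw); MutationAssessor is min-max scaled over
    its published range; probability-scaled programs pass through.
    Raises ``ValueError`` when ``raw`` lies outside the published range.
    """
    if algorithm not in SCORE_BOUNDS:
        raise ValueError(f"unknown algorithm: {algorithm}")
    lo, hi, flip = SCORE_BOUNDS[algorithm]
    if not lo <= raw <= hi:
        raise ValueError(
            f"{algorithm} raw score {raw} outside published range [{lo}, {hi}]"
        )
    unit = (raw - lo) / (hi - lo)
    return 1.0 - unit if flip else unit


def call_deleterious(
    algorithm: str,
    entry: AlgorithmEntry,
    thresholds: CallThresholds | None = None,
) -> Call:
    """Categorical call for one algorithm on one substitution.

    A source-table label wins when present (and preferred); otherwise the
    score is compared with the cutoff.  MutationAssessor is judged on its
    raw scale with a strict > 3.5.  An entry with no usable information
    is ``missing`` -- never silently tolerated.
    """
    if algorithm not in SCORE_BOUNDS:
        raise ValueError(f"unknown algorithm: {algorithm}")
    thresholds = thresholds or CallThresholds()

    if thresholds.prefer_categorical and entry.call is not None:
        damaging = DELETERIOUS_LABELS[algorithm]
        return Call.DELETERIOUS if entry.call in damaging else Call.TOLERATED

    if algorithm == "mutationassessor":
        raw = entry.raw
        if raw is None and entry.rescaled is not None:
            lo, hi, _ = SCORE_BOUNDS[algorithm]
            raw = lo + entry.rescaled * (hi - lo)
        if raw is None:
            return Call.MISSING
        return (
            Call.DELETERIOUS
            if raw > thresholds.mutationassessor_raw
            else Call.TOLERATED
        )

    rescaled = entry.rescaled
    if rescaled is None and entry.raw is not None:
        rescaled = rescale_score(algorithm, entry.raw)
    if rescaled is None:
        return Call.MISSING
    cutoff = thresholds.rescaled_cutoff(algorithm)
    return Call.DELETERIOUS if rescaled >= cutoff else Call.TOLERATED


def consensus_count(
    profile: PredictionProfile, thresholds: CallThresholds | None = None
) -> int:
    """Number of the six programs calling the substitution damaging (0-6).

    Missing entries contribute 0, so a substitution scored by fewer than
    six programs can still reach the >= 3 consensus.
    """
    thresholds = thresholds or CallThresholds()
    return sum(
        call_deleterious(alg, profile.entry(alg), thresholds) is Call.DELETERIOUS
        for alg in ALGORITHMS
    )


def conservation_count(
    profile: PredictionProfile, thresholds: CallThresholds | None = None
) -> int:
    """Number of constraint indicators at or above their cutoff (0-3)."""
    thresholds = thresholds or CallThresholds()
    n = 0
    for indicator in CONSERVATION_INDICATORS:
        value = profile.conservation.get(indicator)
        if value is not None and value >= thresholds.conservation_cutoff(indicator):
            n += 1
    return n


@dataclass(frozen=True)
class StabilityClass:
    direction: str  # stabilizing | destabilizing | neutral
    strength: Optional[str]  # strong | weak | None when neutral

    def __str__(self) -> str:
        if self.direction == "neutral":
            return "neutral"
        return f"{self.direction} ({self.strength})"


def classify_stability(
    ddg: float, strong_cutoff: float = 2.0, neutral_band: float = 0.5
) -> StabilityClass:
    """Ternary stability class from a predicted free-energy change.

    Sign convention: positive ddg = destabilizing.  |ddg| < 0.5 kcal/mol
    is neutral; |ddg| >= 2 kcal/mol is a strong effect, in between weak.
    """
    if abs(ddg) < neutral_band:
        return StabilityClass("neutral", None)
    direction = "destabilizing" if ddg > 0 else "stabilizing"
    strength = "strong" if abs(ddg) >= strong_cutoff else "weak"
    return StabilityClass(direction, strength)
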
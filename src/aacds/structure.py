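"""Automated structure-based residue flags.

Given a protein structure (PDB or mmCIF), a variant residue is screened
on four axes: crystallographic disorder (Cα B-factor > 60 Å², strict),
ligand proximity (minimum heavy-atom distance to any non-water,
non-buffer hetero group, default cutoff 5.0 Å), stability class derived
from an ingested ΔΔG prediction, and sequence-feature context from the
annotation store.  Outputs of external structure servers (stability
centers, surface patches, flexibility classes) are ingested as optional
columns, never computed.

Residue numbering: the variant's ``residue_index`` refers to the
canonical protein sequence; a per-structure offset maps it to the
author numbering used in the coordinate file.  Multi-model (NMR) files
use the first model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.Structure import Structure

from .scores import StabilityClass, classify_stability
from .store import AnnotationStore, features_at
from .types import ProteinVariant

logger = logging.getLogger(__name__)

B_FACTOR_CUTOFF = 60.0  # Å², strict >
LIGAND_CUTOFF = 5.0  # Å

#: Hetero residue names never counted as ligands: water plus common
#: buffer/cryoprotectant components (extendable by callers).
DEFAULT_LIGAND_EXCLUSIONS: frozenset[str] = frozenset(
    {"HOH", "WAT", "DOD", "GOL", "EDO", "PEG", "SO4", "PO4", "CL", "NA", "K", "MG"}
)


def load_structure(path: str | Path, structure_id: str = "structure") -> Structure:
    """Parse a PDB or mmCIF coordinate file (by extension)."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate minor format deviations
        if path.suffix.lower() in (".cif", ".mmcif"):
            return MMCIFParser(QUIET=True).get_structure(structure_id, str(path))
        return PDBParser(QUIET=True).get_structure(structure_id, str(path))


def _first_model(structure: Structure):
    models = list(structure)
    if len(models) > 1:
        logger.info(
            "structure %s has %d models; using the first",
            structure.id,
            len(models),
        )
    return models[0]


def _residue(model, chain_id: str, residue_number: int):
    if chain_id not in model:
        return None
    chain = model[chain_id]
    for residue in chain:
        if residue.id[1] == residue_number and residue.id[0] == " ":
            return residue
    return None


def ca_bfactor(
    structure: Structure, chain_id: str, residue_number: int
) -> Optional[float]:
    """Temperature factor of the residue's Cα atom, or None (with a
    warning) when the residue or its Cα is absent."""
    model = _first_model(structure)
    residue = _residue(model, chain_id, residue_number)
    if residue is None or "CA" not in residue:
        logger.warning(
            "no C-alpha atom for %s/%s in structure %s",
            chain_id,
            residue_number,
            structure.id,
        )
        return None
    return float(residue["CA"].get_bfactor())


def is_high_bfactor(value: Optional[float]) -> Optional[bool]:
    """Disorder flag: strictly above 60 Å²; None propagates missing."""
    if value is None:
        return None
    return value > B_FACTOR_CUTOFF


def ligand_atoms(
    structure: Structure, exclusions: frozenset[str] = DEFAULT_LIGAND_EXCLUSIONS
):
    """Heavy atoms of hetero groups that count as ligands."""
    model = _first_model(structure)
    atoms = []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag == " ":
                continue
            name = residue.get_resname().strip()
            if hetflag == "W" or name in exclusions:
                continue
            for atom in residue:
                if atom.element != "H":
                    atoms.append(atom)
    return atoms


def ligand_proximity(
    structure: Structure,
    chain_id: str,
    residue_number: int,
    cutoff: float = LIGAND_CUTOFF,
    exclusions: frozenset[str] = DEFAULT_LIGAND_EXCLUSIONS,
) -> tuple[Optional[float], bool]:
    """Minimum heavy-atom distance from the residue to any ligand group.

    Returns ``(min_distance, near_ligand)``; with no ligand groups in
    the structure the distance is None and the flag False (a missing
    evidence source never raises a flag).
    """
    model = _first_model(structure)
    residue = _residue(model, chain_id, residue_number)
    if residue is None:
        logger.warning(
            "residue %s/%s absent from structure %s",
            chain_id,
            residue_number,
            structure.id,
        )
        return None, False
    ligands = ligand_atoms(structure, exclusions)
    if not ligands:
        return None, False
    residue_atoms = [atom for atom in residue if atom.element != "H"]
    minimum = min(
        float((atom - other))
        for atom in residue_atoms
        for other in ligands
    )
    return minimum, minimum <= cutoff


@dataclass(frozen=True)
class StructureMapping:
    """Maps a variant's canonical residue index into one structure."""

    pdb_id: str
    chain: str
    #: author residue number = residue_index + offset
    offset: int = 0

    def author_number(self, residue_index: int) -> int:
        return residue_index + self.offset


@dataclass
class StructureContext:
    """Merged structural flags for one variant residue.

    Every flag is None when its evidence source is absent; a flag is
    only ever True on positive evidence.
    """

    pdb_id: Optional[str] = None
    chain: Optional[str] = None
    residue_number: Optional[int] = None
    ca_bfactor: Optional[float] = None
    high_bfactor: Optional[bool] = None
    min_ligand_distance: Optional[float] = None
    near_ligand: Optional[bool] = None
    feature_types: tuple[str, ...] = ()
    stability: Optional[StabilityClass] = None
    surface_patch: Optional[bool] = None
    flexibility_class: Optional[str] = None
    stability_center: Optional[bool] = None
    stabilizing_residue: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.ca_bfactor is not None and self.ca_bfactor < 0:
            raise ValueError("B-factor must be non-negative")
        if self.min_ligand_distance is not None and self.min_ligand_distance < 0:
            raise ValueError("distances must be non-negative")


_INGESTED_BOOL = {"1": True, "0": False, "true": True, "false": False,
                  "yes": True, "no": False}


def _ingested_flag(value: object) -> Optional[bool]:
    if value is None or value == "" or value == ".":
        return None
    return _INGESTED_BOOL.get(str(value).strip().lower())


def residue_flags(
    variant: ProteinVariant,
    store: AnnotationStore,
    structure: Optional[Structure] = None,
    mapping: Optional[StructureMapping] = None,
    ingested: Optional[Mapping[str, object]] = None,
    ligand_cutoff: float = LIGAND_CUTOFF,
) -> StructureContext:
    """Merge feature overlap, B-factor, ligand proximity, stability class
    and ingested external-server columns into one record.

    ``ingested`` may carry ``surface_patch``, ``flexibility_class``,
    ``stability_center`` and ``stabilizing_residue`` columns from
    external structure servers.
    """
    context = StructureContext()
    context.feature_types = tuple(
        feature.feature_type
        for feature in features_at(store, variant.accession, variant.residue_index)
    )
    profile = store.profile(variant.key)
    if profile is not None and profile.ddg is not None:
        context.stability = classify_stability(profile.ddg)

    if structure is not None:
        if mapping is None:
            raise ValueError(
                "a residue mapping is required when a structure is supplied"
            )
        context.pdb_id = mapping.pdb_id
        context.chain = mapping.chain
        context.residue_number = mapping.author_number(variant.residue_index)
        context.ca_bfactor = ca_bfactor(
            structure, mapping.chain, context.residue_number
        )
        context.high_bfactor = is_high_bfactor(context.ca_bfactor)
        context.min_ligand_distance, context.near_ligand = ligand_proximity(
            structure, mapping.chain, context.residue_number, cutoff=ligand_cutoff
        )

    if ingested:
        context.surface_patch = _ingested_flag(ingested.get("surface_patch"))
        context.stability_center = _ingested_flag(ingested.get("stability_center"))
        context.stabilizing_residue = _ingested_flag(
            ingested.get("stabilizing_residue")
        )
        flexibility = ingested.get("flexibility_class")
        if flexibility not in (None, "", "."):
            context.flexibility_class = str(flexibility)
        near = _ingested_flag(ingested.get("near_ligand"))
        if near is not None and context.near_ligand is None:
            context.near_ligand = near

    return context
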
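"""Structure flags: Cα B-factor, ligand proximity (with a brute-force
distance oracle) and the merged residue-flag record."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aacds.scores import StabilityClass
from aacds.store import load_store_from_frames
from aacds.structure import (
    StructureMapping,
    ca_bfactor,
    is_high_bfactor,
    ligand_proximity,
    load_structure,
    residue_flags,
)
from aacds.types import GenomicVariant, ProteinVariant, Zygosity


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, bfactor,
              element, hetatm=False):
    record = "HETATM" if hetatm else "ATOM  "
    return (
        f"{record}{serial:>5} {name:<4}{resname:>4} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfactor:6.2f}"
        f"          {element:>2}\n"
    )


def _write_pdb(path, lines, n_models=1):
    text = ""
    for model in range(1, n_models + 1):
        if n_models > 1:
            text += f"MODEL     {model}\n"
        text += "".join(lines[model - 1] if n_models > 1 else lines)
        if n_models > 1:
            text += "ENDMDL\n"
    text += "END\n"
    path.write_text(text)
    return path


def _protein_lines(bfactor=30.0):
    return [
        _pdb_atom(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, 20.0, "N"),
        _pdb_atom(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, bfactor, "C"),
        _pdb_atom(3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0, 20.0, "C"),
        _pdb_atom(4, "N", "GLY", "A", 2, 3.2, 1.6, 0.0, 20.0, "N"),
        _pdb_atom(5, "CA", "GLY", "A", 2, 4.0, 2.8, 0.0, 25.0, "C"),
    ]


class TestBFactor:
    @pytest.mark.parametrize("value,flag", [(65.0, True), (60.0, False)])
    def test_strict_cutoff(self, tmp_path, value, flag):
        pdb = _write_pdb(tmp_path / "m.pdb", _protein_lines(bfactor=value))
        structure = load_structure(pdb)
        b = ca_bfactor(structure, "A", 1)
        assert b == pytest.approx(value)
        assert is_high_bfactor(b) is flag

    def test_missing_residue_is_missing(self, tmp_path):
        pdb = _write_pdb(tmp_path / "m.pdb", _protein_lines())
        structure = load_structure(pdb)
        assert ca_bfactor(structure, "A", 99) is None
        assert is_high_bfactor(None) is None

    def test_multi_model_uses_first(self, tmp_path):
        models = [_protein_lines(bfactor=70.0), _protein_lines(bfactor=10.0)]
        pdb = _write_pdb(tmp_path / "nmr.pdb", models, n_models=2)
        structure = load_structure(pdb)
        assert ca_bfactor(structure, "A", 1) == pytest.approx(70.0)


class TestLigandProximity:
    def test_nearby_ligand_flagged(self, tmp_path):
        lines = _protein_lines() + [
            _pdb_atom(10, "C1", "GLC", "A", 201, 1.5, 0.0, 3.0, 30.0, "C",
                      hetatm=True),
        ]
        structure = load_structure(_write_pdb(tmp_path / "m.pdb", lines))
        distance, near = ligand_proximity(structure, "A", 1)
        assert distance == pytest.approx(3.0)
        assert near is True

    def test_waters_are_not_ligands(self, tmp_path):
        lines = _protein_lines() + [
            _pdb_atom(10, "O", "HOH", "A", 301, 1.5, 1.0, 0.0, 30.0, "O",
                      hetatm=True),
        ]
        structure = load_structure(_write_pdb(tmp_path / "m.pdb", lines))
        distance, near = ligand_proximity(structure, "A", 1)
        assert distance is None and near is False

    def test_matches_brute_force_scan(self, tmp_path):
        """Minimum residue-to-ligand distance equals an all-pairs scan
        on randomized synthetic structures."""
        rng = np.random.default_rng(8)
        for trial in range(25):
            residue_xyz = rng.uniform(-10, 10, size=(3, 3))
            ligand_xyz = rng.uniform(-10, 10, size=(rng.integers(1, 5), 3))
            lines = [
                _pdb_atom(i + 1, name, "ALA", "A", 1, *residue_xyz[i], 20.0,
                          element)
                for i, (name, element) in enumerate(
                    [("N", "N"), ("CA", "C"), ("C", "C")]
                )
            ] + [
                _pdb_atom(50 + j, "C1", "LIG", "A", 200 + j, *xyz, 20.0, "C",
                          hetatm=True)
                for j, xyz in enumerate(ligand_xyz)
            ]
            structure = load_structure(
                _write_pdb(tmp_path / f"r{trial}.pdb", lines)
            )
            distance, _ = ligand_proximity(structure, "A", 1)
            brute = min(
                float(np.linalg.norm(a - b))
                for a in residue_xyz
                for b in ligand_xyz
            )
            assert distance == pytest.approx(brute, abs=1e-3)


def _variant():
    return ProteinVariant(
        variant=GenomicVariant(chrom="1", pos=100, ref="A", alt="G",
                               rsid="rs1", zygosity=Zygosity.HOM_ALT),
        gene="SYNG00001", accession="SYN00001", transcript="SYNT00001",
        residue_index=1, ref_aa="A", alt_aa="V",
    )


def _store(ddg=None, feature=False):
    frames = {}
    row = {"accession": "SYN00001", "residue_index": "1", "ref_aa": "A",
           "alt_aa": "V", "ddg": "." if ddg is None else str(ddg),
           "ddg_sign_convention": "positive_destabilizing"}
    frames["predictions"] = pd.DataFrame([row])
    if feature:
        frames["sequence_features"] = pd.DataFrame(
            [{"accession": "SYN00001", "feature_type": "DOMAIN",
              "start": "1", "end": "10", "description": "."}]
        )
    return load_store_from_frames(frames)


class TestResidueFlags:
    def test_no_structure_gives_only_sequence_evidence(self):
        context = residue_flags(_variant(), _store(feature=True))
        assert context.feature_types == ("DOMAIN",)
        assert context.ca_bfactor is None
        assert context.high_bfactor is None
        assert context.near_ligand is None
        assert context.surface_patch is None

    def test_stability_class_from_ddg(self):
        """ΔΔG = 1.10 kcal/mol is a weak destabilization."""
        context = residue_flags(_variant(), _store(ddg=1.10))
        assert context.stability == StabilityClass("destabilizing", "weak")

    def test_structure_requires_mapping(self, tmp_path):
        structure = load_structure(
            _write_pdb(tmp_path / "m.pdb", _protein_lines())
        )
        with pytest.raises(ValueError, match="mapping"):
            residue_flags(_variant(), _store(), structure=structure)

    def test_ligand_contact_flag(self, tmp_path):
        """A residue annotated as part of a glucose binding site flags
        near_ligand through the structure route."""
        lines = _protein_lines() + [
            _pdb_atom(10, "C1", "GLC", "A", 201, 1.5, 0.0, 3.0, 30.0, "C",
                      hetatm=True),
        ]
        structure = load_structure(_write_pdb(tmp_path / "m.pdb", lines))
        context = residue_flags(
            _variant(), _store(), structure=structure,
            mapping=StructureMapping(pdb_id="SYNPDB", chain="A", offset=0),
        )
        assert context.near_ligand is True
        assert context.min_ligand_distance == pytest.approx(3.0)

    def test_ablation_never_fabricates_flags(self, tmp_path):
        """Removing each evidence source leaves its flags missing (None),
        never True."""
        bare = residue_flags(_variant(), _store())
        assert bare.feature_types == ()
        assert bare.stability is None
        assert bare.high_bfactor is None and bare.near_ligand is None
        ingested = residue_flags(
            _variant(), _store(),
            ingested={"surface_patch": ".", "flexibility_class": "",
                      "stability_center": None},
        )
        assert ingested.surface_patch is None
        assert ingested.flexibility_class is None
        assert ingested.stability_center is None

    def test_ingested_server_columns(self):
        context = residue_flags(
            _variant(), _store(),
            ingested={"surface_patch": "1", "flexibility_class": "rigid",
                      "stability_center": "0", "stabilizing_residue": "yes",
                      "near_ligand": "1"},
        )
        assert context.surface_patch is True
        assert context.stability_center is False
        assert context.stabilizing_residue is True
        assert context.flexibility_class == "rigid"
        assert context.near_ligand is True  # ingested fills the gap

    def test_determinism(self, tmp_path):
        lines = _protein_lines() + [
            _pdb_atom(10, "C1", "GLC", "A", 201, 4.0, 0.0, 0.0, 65.0, "C",
                      hetatm=True),
        ]
        structure = load_structure(_write_pdb(tmp_path / "m.pdb", lines))
        mapping = StructureMapping(pdb_id="SYNPDB", chain="A")
        a = residue_flags(_variant(), _store(ddg=0.2), structure=structure,
                          mapping=mapping)
        b = residue_flags(_variant(), _store(ddg=0.2), structure=structure,
                          mapping=mapping)
        assert a == b
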
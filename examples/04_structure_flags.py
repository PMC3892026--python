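"""Structure-based residue flags on a small synthetic coordinate file.

Builds a two-residue structure with a bound glucose molecule, then
screens residue 1 for crystallographic disorder (Cα B-factor > 60 Å²)
and ligand proximity (heavy-atom distance <= 5 Å to any non-water
hetero group), and merges the flags with the sequence-feature context
and the ingested stability prediction.
"""

import tempfile
from pathlib import Path

import pandas as pd

from aacds.store import load_store_from_frames
from aacds.structure import StructureMapping, load_structure, residue_flags
from aacds.types import GenomicVariant, ProteinVariant, Zygosity

PDB = """\
ATOM      1 N    ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2 CA   ALA A   1       1.500   0.000   0.000  1.00 67.50           C
ATOM      3 C    ALA A   1       2.000   1.400   0.000  1.00 20.00           C
ATOM      4 N    GLY A   2       3.200   1.600   0.000  1.00 20.00           N
ATOM      5 CA   GLY A   2       4.000   2.800   0.000  1.00 25.00           C
HETATM    6 C1   GLC A 201       1.500   0.000   3.200  1.00 30.00           C
HETATM    7 O    HOH A 301       1.500   1.000   0.000  1.00 30.00           O
END
"""

variant = ProteinVariant(
    variant=GenomicVariant(chrom="1", pos=1000, ref="G", alt="A",
                           rsid="rs_demo", zygosity=Zygosity.HOM_ALT),
    gene="SYNG_DEMO", accession="SYN_DEMO", transcript="SYNT_DEMO",
    residue_index=1, ref_aa="P", alt_aa="S",
)
store = load_store_from_frames({
    "predictions": pd.DataFrame([{
        "accession": "SYN_DEMO", "residue_index": "1",
        "ref_aa": "P", "alt_aa": "S",
        "ddg": "1.10", "ddg_sign_convention": "positive_destabilizing",
    }]),
    "sequence_features": pd.DataFrame([{
        "accession": "SYN_DEMO", "feature_type": "DOMAIN",
        "start": "1", "end": "120", "description": "catalytic domain",
    }]),
})

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.pdb"
    path.write_text(PDB)
    structure = load_structure(path)
    context = residue_flags(
        variant, store, structure=structure,
        mapping=StructureMapping(pdb_id="SYNPDB", chain="A", offset=0),
    )

print(f"sequence features  : {context.feature_types}")
print(f"Calpha B-factor    : {context.ca_bfactor:.1f} A^2 "
      f"(disorder flag: {context.high_bfactor})")
print(f"nearest ligand     : {context.min_ligand_distance:.2f} A "
      f"(near-ligand flag: {context.near_ligand}; waters are ignored)")
print(f"stability class    : {context.stability} "
      "(from the ingested ddG = +1.10 kcal/mol)")
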
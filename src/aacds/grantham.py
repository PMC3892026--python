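"""Grantham physicochemical distance between amino acids.

The distance of Grantham (1974) combines three residue properties --
atomic composition ``c``, polarity ``p`` and molecular volume ``v`` --
into a weighted Euclidean dissimilarity::

    D(i, j) = rho * sqrt(alpha*(c_i-c_j)**2 + beta*(p_i-p_j)**2
                         + gamma*(v_i-v_j)**2)

with ``alpha=1.833``, ``beta=0.1018``, ``gamma=0.000399`` and ``rho``
fixed so that the mean over all 190 unordered residue pairs equals 100.
Distances range from 5 (Ile-Leu) to 215 (Cys-Trp); larger values mark
more radical substitutions.

The integer matrix below is embedded as canonical runtime data; it is
the rounded output of the formula above and matches the published
values for every pair quoted in the variant-prioritization literature.
"""

from __future__ import annotations

from .types import STANDARD_AA, validate_amino_acid

#: Residue property triples (composition, polarity, volume) from
#: Grantham (1974), keyed by one-letter code.
PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

#: Formula weights (composition, polarity, volume).
WEIGHTS: tuple[float, float, float] = (1.833, 0.1018, 0.000399)

# Upper triangle of the symmetric distance matrix, residue order
# ARNDCQEGHILKMFPSTWYV.
_DISTANCES = {
    ("A", "R"): 111,
    ("A", "N"): 111,
    ("A", "D"): 126,
    ("A", "C"): 195,
    ("A", "Q"): 91,
    ("A", "E"): 107,
    ("A", "G"): 60,
    ("A", "H"): 86,
    ("A", "I"): 94,
    ("A", "L"): 96,
    ("A", "K"): 106,
    ("A", "M"): 85,
    ("A", "F"): 113,
    ("A", "P"): 27,
    ("A", "S"): 99,
    ("A", "T"): 58,
    ("A", "W"): 148,
    ("A", "Y"): 112,
    ("A", "V"): 65,
    ("R", "N"): 85,
    ("R", "D"): 96,
    ("R", "C"): 180,
    ("R", "Q"): 43,
    ("R", "E"): 54,
    ("R", "G"): 125,
    ("R", "H"): 29,
    ("R", "I"): 98,
    ("R", "L"): 102,
    ("R", "K"): 26,
    ("R", "M"): 92,
    ("R", "F"): 97,
    ("R", "P"): 103,
    ("R", "S"): 109,
    ("R", "T"): 71,
    ("R", "W"): 101,
    ("R", "Y"): 77,
    ("R", "V"): 96,
    ("N", "D"): 23,
    ("N", "C"): 139,
    ("N", "Q"): 46,
    ("N", "E"): 41,
    ("N", "G"): 79,
    ("N", "H"): 68,
    ("N", "I"): 149,
    ("N", "L"): 153,
    ("N", "K"): 94,
    ("N", "M"): 141,
    ("N", "F"): 158,
    ("N", "P"): 90,
    ("N", "S"): 46,
    ("N", "T"): 65,
    ("N", "W"): 174,
    ("N", "Y"): 142,
    ("N", "V"): 133,
    ("D", "C"): 154,
    ("D", "Q"): 61,
    ("D", "E"): 45,
    ("D", "G"): 94,
    ("D", "H"): 81,
    ("D", "I"): 168,
    ("D", "L"): 172,
    ("D", "K"): 102,
    ("D", "M"): 160,
    ("D", "F"): 177,
    ("D", "P"): 108,
    ("D", "S"): 66,
    ("D", "T"): 85,
    ("D", "W"): 191,
    ("D", "Y"): 160,
    ("D", "V"): 152,
    ("C", "Q"): 154,
    ("C", "E"): 170,
    ("C", "G"): 158,
    ("C", "H"): 174,
    ("C", "I"): 198,
    ("C", "L"): 198,
    ("C", "K"): 202,
    ("C", "M"): 196,
    ("C", "F"): 205,
    ("C", "P"): 169,
    ("C", "S"): 112,
    ("C", "T"): 149,
    ("C", "W"): 215,
    ("C", "Y"): 194,
    ("C", "V"): 191,
    ("Q", "E"): 29,
    ("Q", "G"): 87,
    ("Q", "H"): 24,
    ("Q", "I"): 109,
    ("Q", "L"): 113,
    ("Q", "K"): 53,
    ("Q", "M"): 101,
    ("Q", "F"): 116,
    ("Q", "P"): 75,
    ("Q", "S"): 68,
    ("Q", "T"): 41,
    ("Q", "W"): 130,
    ("Q", "Y"): 99,
    ("Q", "V"): 96,
    ("E", "G"): 98,
    ("E", "H"): 41,
    ("E", "I"): 134,
    ("E", "L"): 139,
    ("E", "K"): 57,
    ("E", "M"): 126,
    ("E", "F"): 140,
    ("E", "P"): 94,
    ("E", "S"): 80,
    ("E", "T"): 66,
    ("E", "W"): 152,
    ("E", "Y"): 123,
    ("E", "V"): 121,
    ("G", "H"): 98,
    ("G", "I"): 136,
    ("G", "L"): 138,
    ("G", "K"): 127,
    ("G", "M"): 127,
    ("G", "F"): 153,
    ("G", "P"): 42,
    ("G", "S"): 55,
    ("G", "T"): 59,
    ("G", "W"): 184,
    ("G", "Y"): 147,
    ("G", "V"): 109,
    ("H", "I"): 94,
    ("H", "L"): 99,
    ("H", "K"): 32,
    ("H", "M"): 86,
    ("H", "F"): 100,
    ("H", "P"): 76,
    ("H", "S"): 89,
    ("H", "T"): 47,
    ("H", "W"): 115,
    ("H", "Y"): 83,
    ("H", "V"): 84,
    ("I", "L"): 5,
    ("I", "K"): 102,
    ("I", "M"): 10,
    ("I", "F"): 21,
    ("I", "P"): 96,
    ("I", "S"): 142,
    ("I", "T"): 89,
    ("I", "W"): 61,
    ("I", "Y"): 33,
    ("I", "V"): 30,
    ("L", "K"): 106,
    ("L", "M"): 14,
    ("L", "F"): 22,
    ("L", "P"): 98,
    ("L", "S"): 144,
    ("L", "T"): 92,
    ("L", "W"): 61,
    ("L", "Y"): 36,
    ("L", "V"): 32,
    ("K", "M"): 95,
    ("K", "F"): 102,
    ("K", "P"): 103,
    ("K", "S"): 121,
    ("K", "T"): 78,
    ("K", "W"): 110,
    ("K", "Y"): 85,
    ("K", "V"): 97,
    ("M", "F"): 29,
    ("M", "P"): 87,
    ("M", "S"): 135,
    ("M", "T"): 81,
    ("M", "W"): 67,
    ("M", "Y"): 35,
    ("M", "V"): 22,
    ("F", "P"): 114,
    ("F", "S"): 155,
    ("F", "T"): 103,
    ("F", "W"): 40,
    ("F", "Y"): 22,
    ("F", "V"): 50,
    ("P", "S"): 73,
    ("P", "T"): 38,
    ("P", "W"): 147,
    ("P", "Y"): 110,
    ("P", "V"): 68,
    ("S", "T"): 58,
    ("S", "W"): 177,
    ("S", "Y"): 143,
    ("S", "V"): 123,
    ("T", "W"): 128,
    ("T", "Y"): 92,
    ("T", "V"): 70,
    ("W", "Y"): 37,
    ("W", "V"): 88,
    ("Y", "V"): 55,
}


def distance(ref_aa: str, alt_aa: str) -> int:
    """Grantham distance between two standard residues.

    Symmetric; identity pairs return 0.  Raises ``ValueError`` for a
    non-standard residue code.
    """
    validate_amino_acid(ref_aa, context="ref_aa")
    validate_amino_acid(alt_aa, context="alt_aa")
    if ref_aa == alt_aa:
        return 0
    key = (ref_aa, alt_aa) if (ref_aa, alt_aa) in _DISTANCES else (alt_aa, ref_aa)
    return _DISTANCES[key]


def matrix() -> dict[tuple[str, str], int]:
    """A copy of the full 190-entry upper-triangle distance table."""
    return dict(_DISTANCES)
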
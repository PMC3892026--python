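"""Score-level building blocks: Grantham distances, score re-scaling,
per-algorithm calls, the 0-6 consensus and the stability class.

The Grantham distance quantifies how radical an amino acid swap is
(5 = Ile/Leu, 215 = Cys/Trp); the consensus counts how many of the six
prediction programs call a substitution damaging (>= 3 defines
"deleterious" in the scheme); the stability class bins a predicted
folding free-energy change (positive = destabilizing).
"""

from aacds import grantham
from aacds.scores import (
    AlgorithmEntry,
    CallThresholds,
    PredictionProfile,
    classify_stability,
    consensus_count,
    rescale_score,
)

for a, b in [("R", "C"), ("N", "S"), ("G", "R"), ("I", "L"), ("C", "W")]:
    print(f"Grantham({a}, {b}) = {grantham.distance(a, b)}")

print(f"\nSIFT raw 0.02 -> rescaled {rescale_score('sift', 0.02):.2f} "
      "(1 = most deleterious)")
print("MutationAssessor raw 4.1 -> rescaled "
      f"{rescale_score('mutationassessor', 4.1):.2f} (damaging above raw 3.5)")

profile = PredictionProfile(entries={
    "sift": AlgorithmEntry(raw=0.01, call="D"),
    "polyphen2_humdiv": AlgorithmEntry(raw=0.98, call="D"),
    "mutationtaster": AlgorithmEntry(call="A"),
    "lrt": AlgorithmEntry(raw=0.45, call="N"),
    "mutationassessor": AlgorithmEntry(raw=1.2, call="L"),
})
count = consensus_count(profile, CallThresholds())
print(f"\nconsensus: {count}/6 programs damaging "
      f"-> {'deleterious' if count >= 3 else 'not deleterious'} "
      "(PolyPhen2 HumVar score missing, counted as not damaging)")

for ddg in (-0.46, 0.58, 1.10, 5.23, -2.77):
    print(f"ddG = {ddg:+.2f} kcal/mol -> {classify_stability(ddg)}")
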
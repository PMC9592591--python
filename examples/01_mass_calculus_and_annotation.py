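"""Composition mass calculus and peak annotation.

N-glycan compositions are written as monosaccharide counts — H hexose,
N N-acetylhexosamine, D deoxyhexose (fucose), A Neu5Ac, G Neu5Gc.
This walkthrough computes neutral and derivatized masses, solves an
observed m/z back to candidate compositions GlycoMod-style, shows a
strictly isobaric ambiguity that no mass tolerance can resolve, and
counts the sialyl-linkage isomers hidden behind one composition.
"""

from glycoatlas.annotation import (
    Tolerance,
    count_sialyl_linkage_isomers,
    solve_compositions,
)
from glycoatlas.core import DerivatizationModel, derivatized_mz, neutral_mass, parse_composition

model = DerivatizationModel()  # protonated, singly charged, methyl-esterified sialic acids

print("== mass calculus ==")
for text in ("H3N2", "H5N2", "H5N4A2"):
    comp = parse_composition(text)
    print(
        f"{text:8s} neutral {neutral_mass(comp):10.4f} Da   "
        f"derivatized [M+H]+ {derivatized_mz(comp, model):10.4f}"
    )

print("\n== de-novo composition solving at 10 ppm ==")
target = parse_composition("H5N4D1A2")
mz = derivatized_mz(target, model)
print(f"observed m/z {mz:.4f} (true composition {target})")
for cand in solve_compositions(mz, model, Tolerance(10, "ppm")):
    print(f"  candidate {str(cand.composition):12s} error {cand.error_da:+.6f} Da")
print(
    "Hex+Neu5Ac and dHex+Neu5Gc share an elemental formula, so the\n"
    "alternatives above are exactly isobaric — a peak-derived library,\n"
    "not a tighter tolerance, is what disambiguates them."
)

print("\n== sialyl-linkage isomers ==")
for text in ("H5N4A2", "H5N4A1", "H6N5A3"):
    comp = parse_composition(text)
    print(
        f"{text}: {count_sialyl_linkage_isomers(comp)} isomers "
        "(antenna occupancy x a2,3/a2,6 linkage)"
    )
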
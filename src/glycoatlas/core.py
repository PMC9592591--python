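"""Glycan composition data model and monoisotopic mass calculus.

N-glycan compositions are described by residue counts in the single-letter
convention used throughout mammalian MALDI-TOF glycomics:

    H = hexose (Man, Gal, Glc)      N = HexNAc (GlcNAc, GalNAc)
    D = deoxyhexose (Fuc)           A = Neu5Ac          G = Neu5Gc

so ``H5N4D1A2`` is a core-fucosylated, disialylated biantennary glycan.
Neutral monoisotopic masses follow from standard residue masses (the
constants GlycoMod uses) plus one water for the free reducing end.  The
glycoblotting sample chemistry — an aminooxy reducing-end tag and methyl
esterification of every sialic-acid carboxyl — is modelled as additive mass
deltas on top of the neutral mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GlycanComposition",
    "ResidueMassTable",
    "DerivatizationModel",
    "CompositionError",
    "parse_composition",
    "neutral_mass",
    "derivatized_mz",
    "PROTON_MASS",
    "SODIUM_CATION_MASS",
]

# Monoisotopic constants (Da).  Residue masses are the dehydrated
# (in-chain) values; a free glycan adds one water.
HEX_MASS = 162.05282
HEXNAC_MASS = 203.07937
DHEX_MASS = 146.05791
NEU5AC_MASS = 291.09542
NEU5GC_MASS = 307.09033
WATER_MASS = 18.01056
PROTON_MASS = 1.00728
SODIUM_CATION_MASS = 22.98922  # Na minus one electron

# Net mass of one methyl ester (-COOH -> -COOCH3): +CH2
METHYL_ESTER_DELTA = 14.01565

_LETTER_ORDER = "HNDAG"
_COMPOSITION_RE = re.compile(r"([HNDAG])(\d+)")


class CompositionError(ValueError):
    """Raised for malformed composition strings or invalid domain inputs."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue counts of an N-glycan composition.

    Counts may describe any partial structure (solver intermediates,
    paucimannose cores); :meth:`is_valid_n_glycan` is the queryable
    predicate for the canonical N-glycan core (n >= 2, h >= 3).
    """

    h: int = 0
    n: int = 0
    d: int = 0
    a: int = 0
    g: int = 0

    def __post_init__(self) -> None:
        for letter in _LETTER_ORDER:
            if getattr(self, letter.lower()) < 0:
                raise CompositionError(f"negative {letter} count in {self!r}")

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.h, self.n, self.d, self.a, self.g)

    @property
    def total_residues(self) -> int:
        return sum(self.counts)

    @property
    def n_sialic(self) -> int:
        """Total sialic acids (Neu5Ac + Neu5Gc)."""
        return self.a + self.g

    def is_valid_n_glycan(self) -> bool:
        """True if the composition contains at least the trimannosyl
        chitobiose core (two HexNAc, three hexoses)."""
        return self.n >= 2 and self.h >= 3

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.h + other.h, self.n + other.n, self.d + other.d,
            self.a + other.a, self.g + other.g,
        )

    def __str__(self) -> str:
        parts = [
            f"{letter}{count}"
            for letter, count in zip(_LETTER_ORDER, self.counts)
            if count > 0
        ]
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GlycanComposition({self or 'empty'})"


def parse_composition(text: str) -> GlycanComposition:
    """Parse a single-letter composition string such as ``"H5N4D1A2"``.

    Each of the letters H, N, D, A, G may appear at most once, followed by
    a positive integer; omitted letters mean zero.  The canonical string
    form (fixed letter order, zeros omitted) round-trips exactly.
    """
    if not isinstance(text, str) or not text:
        raise CompositionError("empty composition string")
    counts = {letter: 0 for letter in _LETTER_ORDER}
    pos = 0
    seen: set[str] = set()
    while pos < len(text):
        m = _COMPOSITION_RE.match(text, pos)
        if m is None:
            raise CompositionError(
                f"malformed composition {text!r}: unexpected token at {text[pos:]!r}"
            )
        letter, digits = m.group(1), m.group(2)
        if letter in seen:
            raise CompositionError(
                f"malformed composition {text!r}: letter {letter} repeated"
            )
        count = int(digits)
        if count == 0:
            raise CompositionError(
                f"malformed composition {text!r}: zero count for {letter}"
            )
        seen.add(letter)
        counts[letter] = count
        pos = m.end()
    return GlycanComposition(
        h=counts["H"], n=counts["N"], d=counts["D"], a=counts["A"], g=counts["G"]
    )


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses (Da) used by the mass calculus."""

    hex: float = HEX_MASS
    hexnac: float = HEXNAC_MASS
    dhex: float = DHEX_MASS
    neu5ac: float = NEU5AC_MASS
    neu5gc: float = NEU5GC_MASS
    water: float = WATER_MASS
    proton: float = PROTON_MASS
    sodium: float = SODIUM_CATION_MASS

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neu5ac", "neu5gc", "water",
                     "proton", "sodium"):
            if getattr(self, name) <= 0:
                raise ValueError(f"residue mass {name} must be positive")


DEFAULT_MASSES = ResidueMassTable()


@dataclass(frozen=True)
class DerivatizationModel:
    """Mass deltas of the glycoblotting chemistry and the MALDI adduct.

    Parameters
    ----------
    tag_delta:
        Net reducing-end mass change (Da) of the aminooxy label,
        condensation water loss included.  The tag's elemental formula is
        instrument-lab specific, so this is a calibration parameter; the
        default 0 analyses underivatized masses.
    methyl_delta:
        Mass added per sialic-acid carboxyl methyl ester, applied a+g
        times (Neu5Ac and Neu5Gc both carry one carboxyl).
    adduct:
        ``"protonated"`` ([M+H]+) or ``"sodiated"`` ([M+Na]+).
    adduct_delta:
        Da added by the charge carrier; defaults to the mass consistent
        with *adduct*.
    charge:
        Positive charge state (MALDI is essentially singly charged).
    """

    tag_delta: float = 0.0
    methyl_delta: float = METHYL_ESTER_DELTA
    adduct: str = "protonated"
    adduct_delta: float | None = None
    charge: int = 1

    def __post_init__(self) -> None:
        if self.adduct not in ("protonated", "sodiated"):
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.adduct_delta is None:
            default = PROTON_MASS if self.adduct == "protonated" else SODIUM_CATION_MASS
            object.__setattr__(self, "adduct_delta", default)

    def with_tag(self, tag_delta: float) -> "DerivatizationModel":
        return replace(self, tag_delta=tag_delta)


def neutral_mass(
    comp: GlycanComposition, masses: ResidueMassTable = DEFAULT_MASSES
) -> float:
    """Neutral monoisotopic mass (Da): sum of residue masses plus water."""
    return (
        comp.h * masses.hex
        + comp.n * masses.hexnac
        + comp.d * masses.dhex
        + comp.a * masses.neu5ac
        + comp.g * masses.neu5gc
        + masses.water
    )


def derivatized_mz(
    comp: GlycanComposition,
    model: DerivatizationModel = DerivatizationModel(),
    masses: ResidueMassTable = DEFAULT_MASSES,
) -> float:
    """m/z of the tagged, methyl-esterified glycan under *model*.

    m/z = (neutral + tag_delta + (a+g) * methyl_delta + adduct_delta) / charge
    """
    m = (
        neutral_mass(comp, masses)
        + model.tag_delta
        + comp.n_sialic * model.methyl_delta
        + model.adduct_delta
    )
    return m / model.charge
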
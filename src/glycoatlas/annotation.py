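"""Composition assignment for MALDI-TOF peak lists.

Two complementary paths mirror common glycomics practice: matching
against a curated library of known mammalian N-glycan compositions, and
GlycoMod-style de-novo enumeration of all compositions whose derivatized
m/z falls inside the mass tolerance.  A small combinatorial model counts
the sialyl-linkage isomer space (alpha-2,3 vs alpha-2,6 at each
sialylated galactose) that a single composition may hide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

from .core import (
    DerivatizationModel,
    GlycanComposition,
    ResidueMassTable,
    DEFAULT_MASSES,
    derivatized_mz,
)

__all__ = [
    "Peak",
    "PeakList",
    "Candidate",
    "Annotation",
    "Tolerance",
    "CompositionBounds",
    "solve_compositions",
    "annotate_peaklist",
    "calibrate_tag_delta",
    "count_sialyl_linkage_isomers",
    "CalibrationError",
]


class CalibrationError(ValueError):
    """Raised when calibration pairs disagree beyond tolerance."""


@dataclass(frozen=True)
class Peak:
    """An observed peak: m/z and isotopic-envelope area."""

    mz: float
    area: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass
class PeakList:
    """Per-sample peak list with metadata and an optional internal standard.

    The internal standard is the spiked non-natural glycan used for
    absolute quantitation; it is held separately so it is never treated
    as an analyte.
    """

    sample_id: str
    class_label: str
    replicate: int
    peaks: list[Peak] = field(default_factory=list)
    internal_standard: Peak | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class Candidate:
    composition: GlycanComposition
    error_da: float
    error_ppm: float


@dataclass
class Annotation:
    """Assignment of a peak to a composition (or to none)."""

    peak: Peak
    candidates: list[Candidate]
    assigned: GlycanComposition | None
    source: str  # "library" | "de_novo" | "none"


@dataclass(frozen=True)
class Tolerance:
    """Mass-match tolerance, in Da or ppm.

    The default +/-0.1 Da suits reflector-mode MALDI peak lists reported
    to two decimals.
    """

    value: float = 0.1
    unit: str = "da"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("da", "ppm"):
            raise ValueError(f"tolerance unit must be 'da' or 'ppm', got {self.unit!r}")

    def window_da(self, mz: float) -> float:
        """Half-width of the acceptance window in Da at the given m/z."""
        return self.value if self.unit == "da" else abs(mz) * self.value * 1e-6


@dataclass(frozen=True)
class CompositionBounds:
    """Inclusive per-letter count ranges searched by the solver."""

    h: tuple[int, int] = (3, 12)
    n: tuple[int, int] = (2, 10)
    d: tuple[int, int] = (0, 5)
    a: tuple[int, int] = (0, 5)
    g: tuple[int, int] = (0, 5)

    def iter_compositions(self) -> Iterable[GlycanComposition]:
        for h, n, d, a, g in product(
            range(self.h[0], self.h[1] + 1),
            range(self.n[0], self.n[1] + 1),
            range(self.d[0], self.d[1] + 1),
            range(self.a[0], self.a[1] + 1),
            range(self.g[0], self.g[1] + 1),
        ):
            yield GlycanComposition(h, n, d, a, g)


DEFAULT_BOUNDS = CompositionBounds()


def is_plausible(comp: GlycanComposition) -> bool:
    """Biosynthetic plausibility filter applied by the solver.

    Requires the N-glycan core (n >= 2, h >= 3), at most one fucose per
    HexNAc (core + antennal), and no more sialic acids than antennae
    plus one — the extra slot admits the monosialyl hybrids (e.g.
    H5N3G1) seen in serum.
    """
    return (
        comp.n >= 2
        and comp.h >= 3
        and comp.d <= comp.n
        and comp.n_sialic <= max(comp.n - 2, 0) + 1
    )


def solve_compositions(
    mz: float,
    model: DerivatizationModel = DerivatizationModel(),
    tol: Tolerance = Tolerance(),
    bounds: CompositionBounds = DEFAULT_BOUNDS,
    masses: ResidueMassTable = DEFAULT_MASSES,
) -> list[Candidate]:
    """Enumerate plausible compositions matching *mz* within *tol*.

    Candidates are sorted by absolute mass error; ties break toward
    fewer total residues, then the canonical composition string, so the
    ranking is fully deterministic.  An empty list is a legitimate
    result, not an error.
    """
    out: list[Candidate] = []
    for comp in bounds.iter_compositions():
        if not is_plausible(comp):
            continue
        theo = derivatized_mz(comp, model, masses)
        err = mz - theo
        if abs(err) <= tol.window_da(mz):
            out.append(Candidate(comp, err, err / theo * 1e6))
    out.sort(
        key=lambda c: (
            abs(c.error_da),
            c.composition.total_residues,
            str(c.composition),
        )
    )
    return out


def annotate_peaklist(
    pl: PeakList,
    model: DerivatizationModel = DerivatizationModel(),
    library: Sequence[GlycanComposition] = (),
    tol: Tolerance = Tolerance(),
    bounds: CompositionBounds = DEFAULT_BOUNDS,
    masses: ResidueMassTable = DEFAULT_MASSES,
    de_novo: bool = True,
) -> list[Annotation]:
    """Annotate every analyte peak of a sample.

    Each peak is first matched against *library*; peaks without a
    library match fall back to de-novo enumeration when *de_novo* is
    set.  The internal-standard peak is excluded by construction (it is
    not part of ``pl.peaks``).
    """
    lib: list[GlycanComposition] = []
    seen: set[GlycanComposition] = set()
    for comp in library:
        if comp in seen:
            warnings.warn(f"duplicate library composition {comp} dropped")
            continue
        seen.add(comp)
        lib.append(comp)
    lib_mz = [(comp, derivatized_mz(comp, model, masses)) for comp in lib]

    annotations: list[Annotation] = []
    for peak in pl.peaks:
        window = tol.window_da(peak.mz)
        cands = [
            Candidate(comp, peak.mz - theo, (peak.mz - theo) / theo * 1e6)
            for comp, theo in lib_mz
            if abs(peak.mz - theo) <= window
        ]
        cands.sort(
            key=lambda c: (
                abs(c.error_da),
                c.composition.total_residues,
                str(c.composition),
            )
        )
        if cands:
            annotations.append(Annotation(peak, cands, cands[0].composition, "library"))
            continue
        if de_novo:
            cands = solve_compositions(peak.mz, model, tol, bounds, masses)
            if cands:
                annotations.append(
                    Annotation(peak, cands, cands[0].composition, "de_novo")
                )
                continue
        annotations.append(Annotation(peak, [], None, "none"))
    return annotations


def calibrate_tag_delta(
    known: tuple[GlycanComposition, float],
    model: DerivatizationModel,
    masses: ResidueMassTable = DEFAULT_MASSES,
    check: tuple[GlycanComposition, float] | None = None,
    check_tol: float = 0.05,
) -> float:
    """Infer the reducing-end tag mass from one (composition, observed m/z) pair.

    The label's elemental formula varies by vendor lot, so the net tag
    delta is recovered algebraically: it is the observed m/z minus the
    tag-free theoretical m/z (times charge).  A second *check* pair, if
    given, must reproduce the same delta within *check_tol* Da.
    """
    comp, observed = known
    base = derivatized_mz(comp, model.with_tag(0.0), masses)
    delta = (observed - base) * model.charge
    if check is not None:
        comp2, observed2 = check
        base2 = derivatized_mz(comp2, model.with_tag(0.0), masses)
        delta2 = (observed2 - base2) * model.charge
        if abs(delta - delta2) > check_tol:
            raise CalibrationError(
                f"calibration pairs disagree: {delta:.4f} vs {delta2:.4f} Da "
                f"(residual {abs(delta - delta2):.4f} > {check_tol} Da)"
            )
    return delta


def count_sialyl_linkage_isomers(comp: GlycanComposition) -> int:
    """Count sialyl regio-isomers of a complex-type composition.

    A complex composition with h hexoses carries h-3 inferred galactose
    sites.  Choosing which sites carry the s = a+g sialic acids and an
    alpha-2,3/alpha-2,6 linkage per occupied site gives
    C(h-3, s) * 2**s distinct assignments (0 when s exceeds the sites).
    The disialyl biantennary H5N4A2 therefore has 4.
    """
    from .glycotyping import classify_type  # local import avoids a cycle

    if classify_type(comp) != "complex":
        raise ValueError(
            f"{comp}: sialyl-linkage isomer model is defined for complex-type only"
        )
    sites = comp.h - 3
    s = comp.n_sialic
    if s > sites:
        return 0
    return math.comb(sites, s) * 2**s
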
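"""Biosynthesis-based glycotyping of N-glycan compositions.

Composition-level rules classify each glycoform along five axes that
summarise where it sits in the mammalian N-glycan maturation pathway:

* glycan type — paucimannose, high-mannose, hybrid or complex;
* most-matured terminal sugar, by the biosynthetic hierarchy
  Neu5Gc/Neu5Ac > Gal > GlcNAc > Man;
* antenna count (HexNAc beyond the chitobiose core, n - 2; a bisecting
  GlcNAc is indistinguishable from an antenna at composition level);
* sialic-acid count (a + g) and fucose count (d).

Per-sample summaries express the absolute abundance falling into each
category as a percentage of the sample's total glycan amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .core import GlycanComposition, parse_composition

__all__ = [
    "GLYCAN_TYPES",
    "TERMINAL_SUGARS",
    "PANELS",
    "GlycotypeAssignment",
    "classify_type",
    "terminal_sugar",
    "assign",
    "summarize",
]

GLYCAN_TYPES = ("paucimannose", "high_mannose", "hybrid", "complex")
TERMINAL_SUGARS = ("Neu5Gc", "Neu5Ac", "Gal", "GlcNAc", "Man")
PANELS = ("glycan_type", "terminal", "antennae", "n_sialic", "n_fuc")


def _require_valid(comp: GlycanComposition) -> None:
    if not comp.is_valid_n_glycan():
        raise ValueError(
            f"{comp or 'empty'}: not a valid N-glycan (needs n >= 2 and h >= 3)"
        )


def classify_type(
    comp: GlycanComposition,
    exceptions: Mapping[str, str] | None = None,
) -> str:
    """Assign one of the four glycan types.

    Rule table (composition-level heuristic):
      n == 2 and h <= 3  -> paucimannose
      n == 2 and h >= 4  -> high_mannose (H4N2 read as a Man4 truncation)
      n >= 3 and h - 3 > n - 2 -> hybrid (more hexoses than antennae can
                                  carry as galactose)
      otherwise          -> complex

    *exceptions* maps canonical composition strings to explicit type
    labels, overriding the rules for structurally known special cases.
    """
    _require_valid(comp)
    if exceptions:
        override = exceptions.get(str(comp))
        if override is not None:
            if override not in GLYCAN_TYPES:
                raise ValueError(f"unknown glycan type override {override!r}")
            return override
    if comp.n == 2:
        return "paucimannose" if comp.h <= 3 else "high_mannose"
    if (comp.h - 3) > (comp.n - 2):
        return "hybrid"
    return "complex"


def terminal_sugar(
    comp: GlycanComposition,
    exceptions: Mapping[str, str] | None = None,
) -> str:
    """Most-matured terminal sugar under the biosynthetic hierarchy.

    Sialic acids dominate; galactose is inferred on hybrid/complex
    glycans with h >= 4 (h == 3 leaves only the trimannosyl core);
    HexNAc beyond the core exposes GlcNAc; otherwise mannose terminates.
    """
    _require_valid(comp)
    if comp.g > 0:
        return "Neu5Gc"
    if comp.a > 0:
        return "Neu5Ac"
    if classify_type(comp, exceptions) in ("complex", "hybrid") and comp.h >= 4:
        return "Gal"
    if comp.n >= 3:
        return "GlcNAc"
    return "Man"


@dataclass(frozen=True)
class GlycotypeAssignment:
    """Full five-axis assignment of one composition."""

    composition: GlycanComposition
    glycan_type: str
    terminal: str
    antennae: int
    n_sialic: int
    n_fuc: int


def assign(
    comp: GlycanComposition,
    exceptions: Mapping[str, str] | None = None,
) -> GlycotypeAssignment:
    _require_valid(comp)
    return GlycotypeAssignment(
        composition=comp,
        glycan_type=classify_type(comp, exceptions),
        terminal=terminal_sugar(comp, exceptions),
        antennae=comp.n - 2,
        n_sialic=comp.n_sialic,
        n_fuc=comp.d,
    )


def summarize(
    matrix,
    exceptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample glycotype percentages for all five panels.

    Parameters
    ----------
    matrix:
        A :class:`~glycoatlas.quantification.ProfileMatrix`.

    Returns
    -------
    Long-format frame with columns ``sample_id, class_label, panel,
    category, percent``.  Within each sample and panel the percentages
    sum to 100 for samples with nonzero total; zero-total samples are
    excluded and reported via the frame's ``attrs["zero_total_samples"]``.
    """
    values = matrix.values
    assignments = {
        comp: assign(parse_composition(comp), exceptions) for comp in values.columns
    }
    category_of = {
        "glycan_type": {c: a.glycan_type for c, a in assignments.items()},
        "terminal": {c: a.terminal for c, a in assignments.items()},
        "antennae": {c: str(a.antennae) for c, a in assignments.items()},
        "n_sialic": {c: str(a.n_sialic) for c, a in assignments.items()},
        "n_fuc": {c: str(a.n_fuc) for c, a in assignments.items()},
    }

    totals = values.sum(axis=1)
    zero_total = totals[totals <= 0].index.tolist()
    rows = []
    for panel in PANELS:
        cats = pd.Series(category_of[panel])
        grouped = values.T.groupby(cats).sum().T  # samples x categories
        pct = grouped.div(totals, axis=0) * 100.0
        for sample_id, row in pct.iterrows():
            if sample_id in zero_total:
                continue
            label = matrix.samples.loc[sample_id, "class_label"]
            for category, percent in row.items():
                rows.append((sample_id, label, panel, category, percent))
    out = pd.DataFrame(
        rows, columns=["sample_id", "class_label", "panel", "category", "percent"]
    )
    out.attrs["zero_total_samples"] = zero_total
    return out


def class_averages(summary: pd.DataFrame) -> pd.DataFrame:
    """Average the per-sample percentages across replicates of each class."""
    return (
        summary.groupby(["class_label", "panel", "category"], as_index=False)["percent"]
        .mean()
    )
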
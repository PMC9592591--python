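"""Internal-standard absolute quantitation and profile-matrix assembly.

A known amount of a non-natural glycan is spiked into every sample
before glycan capture, so analyte amounts follow from the ratio of
isotopic-envelope areas:

    amount_i = (area_i / area_IS) * IS_amount

in pmol per 100 ug total protein.  A detection filter then keeps only
glycoforms observed reproducibly (by default in >= 3 replicates of at
least one sample class), and the retained records are assembled into a
samples x glycoforms matrix.  Non-detected cells carry amount 0 with an
explicit detection mask, so totals treat them as zero while glycoform
counts use detection, not positivity of a float.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation, PeakList
from .core import GlycanComposition

__all__ = [
    "QuantRecord",
    "QuantitationError",
    "ProfileMatrix",
    "quantify",
    "quant_table",
    "detection_filter",
    "build_matrix",
    "profile_summary",
]

QUANT_COLUMNS = ["sample_id", "class_label", "replicate", "composition", "amount"]


class QuantitationError(ValueError):
    """Raised when a sample cannot be quantified (e.g. no internal standard)."""


@dataclass(frozen=True)
class QuantRecord:
    """Absolute amount of one glycoform in one sample (pmol / 100 ug protein)."""

    sample_id: str
    composition: GlycanComposition
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")


def quantify(
    pl: PeakList,
    annotations: Sequence[Annotation],
    is_amount: float = 10.0,
    protein_factor: float = 1.0,
) -> list[QuantRecord]:
    """Convert annotated peak areas to absolute amounts.

    *is_amount* is the spiked internal-standard amount in pmol (10 pmol
    in the tissue/exosome glycoblotting protocol).  *protein_factor*
    rescales to the per-100-ug-protein basis when the input was not
    prepared from 100 ug (default 1).  Peaks sharing an assigned
    composition are summed.  A missing or zero-area internal standard
    invalidates the whole sample.
    """
    if is_amount <= 0:
        raise ValueError("is_amount must be positive")
    if pl.internal_standard is None or pl.internal_standard.area <= 0:
        raise QuantitationError(
            f"sample {pl.sample_id}: missing or zero-area internal standard"
        )
    area_is = pl.internal_standard.area
    amounts: dict[GlycanComposition, float] = {}
    for ann in annotations:
        if ann.assigned is None:
            continue
        amounts[ann.assigned] = (
            amounts.get(ann.assigned, 0.0)
            + ann.peak.area / area_is * is_amount * protein_factor
        )
    return [
        QuantRecord(pl.sample_id, comp, amount)
        for comp, amount in sorted(amounts.items(), key=lambda kv: str(kv[0]))
    ]


def quant_table(
    records_by_sample: Iterable[tuple[PeakList, Sequence[QuantRecord]]],
) -> pd.DataFrame:
    """Assemble per-sample records into the long-format quant table."""
    rows = []
    for pl, records in records_by_sample:
        for rec in records:
            rows.append(
                (pl.sample_id, pl.class_label, pl.replicate, str(rec.composition),
                 rec.amount)
            )
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def detection_filter(
    table: pd.DataFrame,
    min_detections: int = 3,
    scope: Literal["within-any-group", "global"] = "within-any-group",
) -> tuple[list[str], pd.DataFrame]:
    """Keep glycoforms detected reproducibly.

    ``within-any-group`` (default) retains a composition when at least
    one class detects it (> 0) in >= *min_detections* of its
    replicates — the 'three independent experiments' rule applied per
    organ.  ``global`` counts detections over all samples instead.

    Returns the retained composition strings (sorted) and a per-
    composition tally frame (columns ``composition, max_group_detections,
    global_detections, retained``).
    """
    if min_detections < 1:
        raise ValueError("min_detections must be >= 1")
    detected = table[table["amount"] > 0]
    global_counts = detected.groupby("composition")["sample_id"].nunique()
    group_counts = (
        detected.groupby(["composition", "class_label"])["sample_id"]
        .nunique()
        .groupby("composition")
        .max()
    )
    all_comps = sorted(table["composition"].unique())
    tally = pd.DataFrame(
        {
            "composition": all_comps,
            "max_group_detections": [int(group_counts.get(c, 0)) for c in all_comps],
            "global_detections": [int(global_counts.get(c, 0)) for c in all_comps],
        }
    )
    if scope == "within-any-group":
        tally["retained"] = tally["max_group_detections"] >= min_detections
    elif scope == "global":
        tally["retained"] = tally["global_detections"] >= min_detections
    else:
        raise ValueError(f"unknown filter scope {scope!r}")
    retained = tally.loc[tally["retained"], "composition"].tolist()
    return retained, tally


@dataclass
class ProfileMatrix:
    """Samples x glycoforms abundance grid with class labels and a
    detection mask.

    ``values`` holds amounts (pmol / 100 ug protein) with 0 for
    non-detections; ``mask`` is True where the glycoform was detected;
    ``samples`` is indexed by sample_id with columns ``class_label`` and
    ``replicate``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must share index and columns")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the sample index")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("sample and composition identifiers must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_glycoforms(self) -> int:
        return self.values.shape[1]

    @property
    def class_labels(self) -> pd.Series:
        return self.samples["class_label"]

    def subset_classes(self, labels: Sequence[str]) -> "ProfileMatrix":
        keep = self.samples["class_label"].isin(labels)
        return ProfileMatrix(
            self.values.loc[keep].copy(),
            self.mask.loc[keep].copy(),
            self.samples.loc[keep].copy(),
        )


def build_matrix(table: pd.DataFrame, retained: Sequence[str]) -> ProfileMatrix:
    """Pivot the quant table into a ProfileMatrix over *retained* glycoforms.

    Absent (sample, composition) pairs become 0 with mask False.
    Duplicate records for a pair are an error (they should have been
    summed upstream).
    """
    dup = table.duplicated(subset=["sample_id", "composition"], keep=False)
    if dup.any():
        pairs = table.loc[dup, ["sample_id", "composition"]].drop_duplicates()
        raise ValueError(
            "duplicate (sample, composition) records: "
            + ", ".join(f"({r.sample_id}, {r.composition})" for r in pairs.itertuples())
        )
    sub = table[table["composition"].isin(set(retained))]
    samples = (
        table[["sample_id", "class_label", "replicate"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .sort_index()
    )
    values = (
        sub.pivot(index="sample_id", columns="composition", values="amount")
        .reindex(index=samples.index, columns=list(retained))
    )
    mask = values.notna() & (values > 0)
    values = values.fillna(0.0)
    values.columns.name = None
    mask.columns.name = None
    return ProfileMatrix(values, mask, samples)


def profile_summary(matrix: ProfileMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate totals/counts and their per-class medians.

    Per replicate: total amount (sum over glycoforms, non-detections
    counting 0) and the number of detected glycoforms.  Per class the
    median of each across replicates is reported, matching how the
    atlas summarises five animals per organ.
    """
    per_replicate = pd.DataFrame(
        {
            "class_label": matrix.samples["class_label"],
            "replicate": matrix.samples["replicate"],
            "total": matrix.values.sum(axis=1),
            "n_glycoforms": matrix.mask.sum(axis=1).astype(int),
        }
    )
    per_class = (
        per_replicate.groupby("class_label")
        .agg(median_total=("total", "median"), median_n_glycoforms=("n_glycoforms", "median"))
        .reset_index()
    )
    return per_replicate, per_class
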
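"""Delimited-text I/O for peak lists, quant tables and profile matrices.

All on-disk formats are UTF-8 delimited text:

* **Peak lists** — TSV with columns ``sample_id, class_label,
  replicate, mz, area, is_internal_standard`` (0/1, at most one IS row
  per sample).
* **Composition library** — TSV with a ``composition`` column and an
  optional ``compound_number``.
* **Quant table** — TSV with columns ``sample_id, class_label,
  replicate, composition, amount``.
* **Profile matrix** — wide CSV, one row per sample with metadata
  columns followed by one column per glycoform; empty cells mean
  not detected, so the matrix round-trips with its mask.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import Peak, PeakList
from .core import GlycanComposition, parse_composition
from .quantification import QUANT_COLUMNS, ProfileMatrix

__all__ = [
    "read_peaklists",
    "write_peaklists",
    "read_library",
    "write_library",
    "read_quant_table",
    "write_quant_table",
    "read_matrix",
    "write_matrix",
]

PEAKLIST_COLUMNS = [
    "sample_id", "class_label", "replicate", "mz", "area", "is_internal_standard",
]
META_COLUMNS = ["sample_id", "class_label", "replicate"]


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending row."""


def read_peaklists(path: str | Path) -> list[PeakList]:
    """Read per-sample peak lists from a TSV file.

    Rows are grouped by ``sample_id`` in order of first appearance.
    Errors name the 1-based data row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in PEAKLIST_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        by_sample: dict[str, PeakList] = {}
        for rownum, row in enumerate(reader, start=1):
            sid = row["sample_id"]
            try:
                mz = float(row["mz"])
                area = float(row["area"])
                replicate = int(row["replicate"])
                is_standard = int(row["is_internal_standard"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: row {rownum}: {exc}") from exc
            if sid not in by_sample:
                by_sample[sid] = PeakList(
                    sample_id=sid,
                    class_label=row["class_label"],
                    replicate=replicate,
                    peaks=[],
                )
            pl = by_sample[sid]
            try:
                peak = Peak(mz, area)
            except ValueError as exc:
                raise FormatError(f"{path}: row {rownum}: {exc}") from exc
            if is_standard:
                if pl.internal_standard is not None:
                    raise FormatError(
                        f"{path}: row {rownum}: duplicate internal-standard row "
                        f"for sample {sid}"
                    )
                pl.internal_standard = peak
            else:
                pl.peaks.append(peak)
    return list(by_sample.values())


def write_peaklists(peaklists: Sequence[PeakList], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PEAKLIST_COLUMNS)
        for pl in peaklists:
            rows = [(p, 0) for p in pl.peaks]
            if pl.internal_standard is not None:
                rows.append((pl.internal_standard, 1))
            for peak, flag in rows:
                writer.writerow(
                    [pl.sample_id, pl.class_label, pl.replicate,
                     repr(peak.mz), repr(peak.area), flag]
                )


def read_library(path: str | Path) -> list[GlycanComposition]:
    """Read a known-composition library (TSV: composition[, compound_number])."""
    df = pd.read_csv(path, sep="\t")
    if "composition" not in df.columns:
        raise FormatError(f"{path}: missing 'composition' column")
    return [parse_composition(text) for text in df["composition"]]


def write_library(
    library: Sequence[GlycanComposition],
    path: str | Path,
    compound_numbers: Sequence[int] | None = None,
) -> None:
    df = pd.DataFrame({"composition": [str(c) for c in library]})
    if compound_numbers is not None:
        df["compound_number"] = list(compound_numbers)
    df.to_csv(path, sep="\t", index=False)


def read_quant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df[QUANT_COLUMNS]


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    table[QUANT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a profile matrix as wide CSV; not-detected cells are empty."""
    wide = matrix.values.where(matrix.mask)
    out = pd.concat([matrix.samples[["class_label", "replicate"]], wide], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_matrix(path: str | Path) -> ProfileMatrix:
    df = pd.read_csv(path, index_col="sample_id")
    df.index.name = None
    for col in ("class_label", "replicate"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing '{col}' column")
    samples = df[["class_label", "replicate"]].copy()
    samples["replicate"] = samples["replicate"].astype(int)
    values = df.drop(columns=["class_label", "replicate"]).astype(float)
    mask = values.notna()
    return ProfileMatrix(values.fillna(0.0), mask, samples)
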
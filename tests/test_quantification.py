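"""Internal-standard quantitation, detection filtering and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from glycoatlas.annotation import Annotation, Candidate, Peak, PeakList
from glycoatlas.core import parse_composition
from glycoatlas.quantification import (
    ProfileMatrix,
    QuantitationError,
    build_matrix,
    detection_filter,
    profile_summary,
    quant_table,
    quantify,
)
from glycoatlas.synthetic import SyntheticAtlasSpec, generate_atlas


def _annotated(pl, assignments):
    """Build trivial annotations (peak i -> composition i)."""
    return [
        Annotation(peak, [Candidate(comp, 0.0, 0.0)], comp, "library")
        for peak, comp in zip(pl.peaks, assignments)
    ]


def _peaklist(areas, is_area=1000.0, sample_id="s1", label="brain", replicate=1):
    peaks = [Peak(900.0 + i, a) for i, a in enumerate(areas)]
    return PeakList(sample_id, label, replicate, peaks, Peak(2446.85, is_area))


def test_amount_is_area_ratio_times_standard():
    pl = _peaklist([500.0])
    recs = quantify(pl, _annotated(pl, [parse_composition("H3N2")]), is_amount=10.0)
    assert recs[0].amount == pytest.approx(5.0)


def test_area_equal_to_standard_gives_standard_amount():
    pl = _peaklist([1000.0])
    recs = quantify(pl, _annotated(pl, [parse_composition("H3N2")]), is_amount=7.5)
    assert recs[0].amount == pytest.approx(7.5)


@given(
    st.lists(st.floats(1e-3, 1e6), min_size=3, max_size=3),
    st.floats(0.1, 1e3),
    st.floats(1e-2, 1e4),
)
def test_quantitation_is_scale_invariant_and_linear(areas, scale, is_amount):
    comps = [parse_composition(t) for t in ("H3N2", "H5N2", "H5N4A2")]
    pl1 = _peaklist(areas, is_area=1000.0)
    pl2 = _peaklist([a * scale for a in areas], is_area=1000.0 * scale)
    r1 = quantify(pl1, _annotated(pl1, comps), is_amount=is_amount)
    r2 = quantify(pl2, _annotated(pl2, comps), is_amount=is_amount)
    for a, b in zip(r1, r2):
        assert a.amount == pytest.approx(b.amount, rel=1e-9)
    # amounts keep the area ratios regardless of is_amount
    amounts = {str(r.composition): r.amount for r in r1}
    by_comp = dict(zip(("H3N2", "H5N2", "H5N4A2"), areas))
    for c1 in by_comp:
        for c2 in by_comp:
            assert amounts[c1] / amounts[c2] == pytest.approx(
                by_comp[c1] / by_comp[c2], rel=1e-9
            )


def test_missing_or_zero_internal_standard_fails_whole_sample():
    pl = _peaklist([10.0])
    pl.internal_standard = None
    with pytest.raises(QuantitationError):
        quantify(pl, _annotated(pl, [parse_composition("H3N2")]))
    pl.internal_standard = Peak(2446.85, 0.0)
    with pytest.raises(QuantitationError):
        quantify(pl, _annotated(pl, [parse_composition("H3N2")]))


def test_peaks_sharing_a_composition_are_summed():
    pl = _peaklist([100.0, 200.0])
    comp = parse_composition("H3N2")
    recs = quantify(pl, _annotated(pl, [comp, comp]), is_amount=10.0)
    assert len(recs) == 1
    assert recs[0].amount == pytest.approx(3.0)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "class_label", "replicate", "composition", "amount"]
    )


def test_filter_retains_composition_detected_in_three_replicates_of_one_class():
    rows = [(f"m_{r}", "muscle", r, "H3N2", 1.0) for r in (1, 2, 3)]
    retained, _ = detection_filter(_table(rows), min_detections=3)
    assert retained == ["H3N2"]


def test_filter_scope_contrast_two_classes_two_detections_each():
    rows = [
        (f"{c}_{r}", c, r, "H5N2", 1.0) for c in ("muscle", "liver") for r in (1, 2)
    ]
    within, _ = detection_filter(_table(rows), 3, scope="within-any-group")
    global_, _ = detection_filter(_table(rows), 3, scope="global")
    assert within == []
    assert global_ == ["H5N2"]


def test_filter_monotone_in_min_detections(atlas):
    matrix, _ = atlas
    table = matrix.values.stack().rename("amount").reset_index()
    table.columns = ["sample_id", "composition", "amount"]
    table = table.merge(
        matrix.samples.reset_index(names="sample_id"), on="sample_id"
    )
    prev = None
    for k in (1, 2, 3, 4, 5):
        retained, _ = detection_filter(table, min_detections=k)
        if prev is not None:
            assert set(retained) <= set(prev)
        prev = retained


def test_filter_matches_brute_force_recount(atlas):
    matrix, _ = atlas
    table = matrix.values.stack().rename("amount").reset_index()
    table.columns = ["sample_id", "composition", "amount"]
    table = table.merge(matrix.samples.reset_index(names="sample_id"), on="sample_id")
    retained, tally = detection_filter(table, min_detections=3)
    # independent recount with plain loops
    expected = []
    for comp in sorted(table["composition"].unique()):
        best = 0
        for cls in table["class_label"].unique():
            sub = table[
                (table["composition"] == comp)
                & (table["class_label"] == cls)
                & (table["amount"] > 0)
            ]
            best = max(best, sub["sample_id"].nunique())
        if best >= 3:
            expected.append(comp)
    assert retained == expected


def test_build_matrix_shape_and_zero_fill():
    rows = [
        ("s1", "brain", 1, "H3N2", 2.0),
        ("s1", "brain", 1, "H5N2", 1.0),
        ("s2", "liver", 1, "H3N2", 4.0),
    ]
    m = build_matrix(_table(rows), ["H3N2", "H5N2"])
    assert m.values.shape == (2, 2)
    assert m.values.loc["s2", "H5N2"] == 0.0
    assert not m.mask.loc["s2", "H5N2"]
    assert m.mask.loc["s1", "H5N2"]


def test_build_matrix_single_cell():
    m = build_matrix(_table([("s1", "brain", 1, "H3N2", 2.0)]), ["H3N2"])
    assert m.values.shape == (1, 1)


def test_build_matrix_conserves_totals(atlas):
    matrix, _ = atlas
    table = matrix.values.stack().rename("amount").reset_index()
    table.columns = ["sample_id", "composition", "amount"]
    table = table.merge(matrix.samples.reset_index(names="sample_id"), on="sample_id")
    table = table[table["amount"] > 0]
    retained = sorted(table["composition"].unique())
    m = build_matrix(table, retained)
    col_sums = m.values.sum(axis=0)
    rec_sums = table.groupby("composition")["amount"].sum()
    for comp in retained:
        assert col_sums[comp] == pytest.approx(rec_sums[comp])
    assert m.values.to_numpy().sum() == pytest.approx(table["amount"].sum())


def test_build_matrix_rejects_duplicates():
    rows = [("s1", "brain", 1, "H3N2", 2.0), ("s1", "brain", 1, "H3N2", 3.0)]
    with pytest.raises(ValueError, match="duplicate"):
        build_matrix(_table(rows), ["H3N2"])


def test_per_class_median_total():
    rows = []
    for r, total in enumerate([80.0, 82.8, 85.0, 90.0, 79.0], start=1):
        rows.append((f"m_{r}", "muscle", r, "H3N2", total))
    m = build_matrix(_table(rows), ["H3N2"])
    _, per_class = profile_summary(m)
    assert per_class.loc[0, "median_total"] == pytest.approx(82.8)


def test_single_replicate_median_is_that_replicate():
    m = build_matrix(_table([("s1", "brain", 1, "H3N2", 42.0)]), ["H3N2"])
    _, per_class = profile_summary(m)
    assert per_class.loc[0, "median_total"] == pytest.approx(42.0)
    assert per_class.loc[0, "median_n_glycoforms"] == 1


def test_profile_summary_matches_recount(atlas):
    matrix, _ = atlas
    per_replicate, per_class = profile_summary(matrix)
    for sample_id, row in matrix.values.iterrows():
        assert per_replicate.loc[sample_id, "total"] == pytest.approx(row.sum())
        assert per_replicate.loc[sample_id, "n_glycoforms"] == int(
            matrix.mask.loc[sample_id].sum()
        )
    for rec in per_class.itertuples():
        sub = per_replicate[per_replicate["class_label"] == rec.class_label]
        assert rec.median_total == pytest.approx(sub["total"].median())
        assert rec.median_n_glycoforms == pytest.approx(sub["n_glycoforms"].median())
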
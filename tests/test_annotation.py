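"""Peak annotation: de-novo composition solving, library matching,
tag calibration and sialyl-isomer counting."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from glycoatlas.annotation import (
    CalibrationError,
    CompositionBounds,
    Peak,
    PeakList,
    Tolerance,
    annotate_peaklist,
    calibrate_tag_delta,
    count_sialyl_linkage_isomers,
    is_plausible,
    solve_compositions,
)
from glycoatlas.core import DerivatizationModel, GlycanComposition, derivatized_mz, parse_composition
from glycoatlas.synthetic import SyntheticAtlasSpec, emit_peaklists, generate_atlas

MODEL = DerivatizationModel()
SMALL_BOUNDS = CompositionBounds(h=(3, 7), n=(2, 6), d=(0, 3), a=(0, 3), g=(0, 3))


def oracle_solve(mz, tol_da, bounds):
    """Naive exhaustive filter over the bounded grid (independent loop)."""
    out = []
    for h, n, d, a, g in itertools.product(
        range(bounds.h[0], bounds.h[1] + 1),
        range(bounds.n[0], bounds.n[1] + 1),
        range(bounds.d[0], bounds.d[1] + 1),
        range(bounds.a[0], bounds.a[1] + 1),
        range(bounds.g[0], bounds.g[1] + 1),
    ):
        comp = GlycanComposition(h, n, d, a, g)
        if not (n >= 2 and h >= 3 and d <= n and a + g <= max(n - 2, 0) + 1):
            continue
        if abs(mz - derivatized_mz(comp, MODEL)) <= tol_da:
            out.append(comp)
    return set(out)


def test_unique_solution_for_core_pentasaccharide():
    mz = derivatized_mz(parse_composition("H3N2"), MODEL)
    cands = solve_compositions(mz, MODEL, Tolerance(0.5, "da"))
    assert [str(c.composition) for c in cands] == ["H3N2"]


def test_zero_mz_yields_empty_list():
    assert solve_compositions(0.001, MODEL, Tolerance(0.5, "da")) == []


def test_ppm_tolerance_matches_oracle_including_exact_isobars():
    """Hex+Neu5Ac and dHex+Neu5Gc share an elemental composition, so the
    disialyl fucosylated biantennary has strictly isobaric alternatives
    that no mass tolerance can separate; the solver must return exactly
    the oracle's candidate set with the true composition at zero error."""
    comp = parse_composition("H5N4D1A2")
    mz = derivatized_mz(comp, MODEL)
    cands = solve_compositions(mz, MODEL, Tolerance(10, "ppm"))
    oracle = oracle_solve(mz, Tolerance(10, "ppm").window_da(mz), CompositionBounds())
    assert {c.composition for c in cands} == oracle
    assert comp in oracle
    zero_error = {c.composition for c in cands if abs(c.error_da) < 1e-9}
    assert comp in zero_error


@pytest.mark.parametrize("target", ["H3N2", "H5N4A2", "H4N3D1G1", "H7N6D2A3"])
@pytest.mark.parametrize("tol_da", [0.2, 2.0])
def test_solver_matches_exhaustive_oracle(target, tol_da):
    mz = derivatized_mz(parse_composition(target), MODEL)
    got = {c.composition for c in solve_compositions(mz, MODEL, Tolerance(tol_da, "da"), SMALL_BOUNDS)}
    assert got == oracle_solve(mz, tol_da, SMALL_BOUNDS)


def test_enlarging_tolerance_never_removes_candidates():
    mz = derivatized_mz(parse_composition("H5N4A1"), MODEL)
    prev: set = set()
    for tol in (0.01, 0.1, 1.0, 5.0, 20.0):
        got = {c.composition for c in solve_compositions(mz, MODEL, Tolerance(tol, "da"), SMALL_BOUNDS)}
        assert prev <= got
        prev = got


def test_candidates_sorted_by_error_then_size_then_string():
    mz = derivatized_mz(parse_composition("H5N4A1"), MODEL)
    cands = solve_compositions(mz, MODEL, Tolerance(30.0, "da"), SMALL_BOUNDS)
    keys = [
        (abs(c.error_da), c.composition.total_residues, str(c.composition))
        for c in cands
    ]
    assert keys == sorted(keys)
    assert len(cands) > 1  # the wide window must actually exercise the ordering


def test_non_positive_tolerance_rejected():
    with pytest.raises(ValueError):
        Tolerance(0.0, "da")
    with pytest.raises(ValueError):
        Tolerance(-1.0, "ppm")


def test_library_match_preferred_over_de_novo():
    comp = parse_composition("H5N2")
    pl = PeakList("s1", "brain", 1, [Peak(derivatized_mz(comp, MODEL), 100.0)])
    anns = annotate_peaklist(pl, MODEL, [comp], Tolerance(0.2, "da"))
    assert anns[0].assigned == comp and anns[0].source == "library"


def test_unmatchable_peak_assigned_none():
    pl = PeakList("s1", "brain", 1, [Peak(900.0, 10.0)])
    anns = annotate_peaklist(pl, MODEL, [parse_composition("H3N2")],
                             Tolerance(0.2, "da"), de_novo=False)
    assert anns[0].assigned is None and anns[0].source == "none"


def test_duplicate_library_entries_warn_and_deduplicate():
    comp = parse_composition("H3N2")
    pl = PeakList("s1", "brain", 1, [Peak(derivatized_mz(comp, MODEL), 1.0)])
    with pytest.warns(UserWarning, match="duplicate library"):
        anns = annotate_peaklist(pl, MODEL, [comp, comp], Tolerance(0.2, "da"))
    assert len(anns[0].candidates) == 1


def test_atlas_round_trip_all_library_assigned():
    matrix, truth = generate_atlas(SyntheticAtlasSpec(seed=3))
    peaklists = emit_peaklists(matrix, MODEL)
    library = truth["library"]
    for pl in peaklists[:10]:
        anns = annotate_peaklist(pl, MODEL, library, Tolerance(0.01, "da"))
        assert len(anns) == len(pl.peaks)
        assert all(a.source == "library" for a in anns)
        # the recovered composition set equals the detected set exactly
        recovered = {str(a.assigned) for a in anns}
        detected = {c for c, flag in matrix.mask.loc[pl.sample_id].items() if flag}
        assert recovered == detected


@pytest.mark.parametrize("tag", [389.2, 0.0])
def test_tag_calibration_inverts_exactly(tag):
    comp = parse_composition("H5N4A2")
    observed = derivatized_mz(comp, MODEL.with_tag(tag))
    assert calibrate_tag_delta((comp, observed), MODEL) == pytest.approx(tag, abs=1e-9)


def test_tag_calibration_consistency_check():
    c1, c2 = parse_composition("H5N4A2"), parse_composition("H3N2")
    obs1 = derivatized_mz(c1, MODEL.with_tag(389.2)) + 0.01
    obs2 = derivatized_mz(c2, MODEL.with_tag(389.2)) - 0.01
    delta = calibrate_tag_delta((c1, obs1), MODEL, check=(c2, obs2), check_tol=0.05)
    assert delta == pytest.approx(389.21, abs=1e-6)
    with pytest.raises(CalibrationError, match="residual"):
        calibrate_tag_delta((c1, obs1), MODEL, check=(c2, obs2 + 1.0), check_tol=0.05)


def oracle_isomers(comp):
    """Enumerate (sialylated-site set, per-site linkage) assignments."""
    sites = comp.h - 3
    s = comp.a + comp.g
    count = 0
    for occupied in itertools.combinations(range(sites), s):
        count += len(list(itertools.product(["a2,3", "a2,6"], repeat=s)))
    return count


@pytest.mark.parametrize(
    "text,expected",
    [("H5N4A2", 4), ("H5N4", 1), ("H5N4A1", 4), ("H4N4A2", 0), ("H6N5A3", 8)],
)
def test_sialyl_linkage_isomer_counts(text, expected):
    comp = parse_composition(text)
    assert count_sialyl_linkage_isomers(comp) == expected
    if comp.a + comp.g <= comp.h - 3:
        assert expected == oracle_isomers(comp)


def test_isomer_count_requires_complex_type():
    with pytest.raises(ValueError, match="complex"):
        count_sialyl_linkage_isomers(parse_composition("H9N2"))


@given(st.integers(4, 9), st.integers(0, 4))
def test_isomer_count_matches_combinatorial_formula(h, s):
    comp = GlycanComposition(h=h, n=max(s + 2, h - 2), a=s)
    if not is_plausible(comp):
        return
    from glycoatlas.glycotyping import classify_type

    if classify_type(comp) != "complex":
        return
    expected = math.comb(h - 3, s) * 2**s if s <= h - 3 else 0
    assert count_sialyl_linkage_isomers(comp) == expected
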
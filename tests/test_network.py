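"""Series/parallel composition algebra and recipe evaluation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carotidwk.network import (RecipeEntry, RecipeTable, ReductionNode,
                               combine_parallel, combine_series,
                               compare_to_printed, evaluate_recipes)
from carotidwk.vessel import LumpedElement

elements = st.builds(
    LumpedElement,
    resistance=st.floats(min_value=1e5, max_value=1e13),
    compliance=st.floats(min_value=1e-19, max_value=1e-11),
)


def test_series_single_element_identity():
    e = LumpedElement(1.0e8, 2.0e-14)
    assert combine_series([e]) == e
    assert combine_parallel([e]) == e


def test_series_matches_tabulated_step():
    # M4 chain step: distal-M4 lump in series with the M4 trunk
    out = combine_series([LumpedElement(1.40e8, 1.67e-14),
                          LumpedElement(1.87e9, 3.80e-15)])
    assert out.resistance == pytest.approx(2.01e9, rel=0.01)
    assert out.compliance == pytest.approx(3.10e-15, rel=0.01)


def test_parallel_matches_tabulated_steps():
    lls = LumpedElement(6.40e10, 6.60e-16)
    out = combine_parallel([lls], factors=[9])
    assert out.resistance == pytest.approx(7.11e9, rel=0.01)
    assert out.compliance == pytest.approx(5.94e-15, rel=0.01)
    perf = LumpedElement(2.79e10, 1.10e-16)
    out = combine_parallel([perf], factors=[7.6])  # fractional multiplicity
    assert out.resistance == pytest.approx(3.67e9, rel=0.01)
    assert out.compliance == pytest.approx(8.36e-16, rel=0.01)


@given(e=elements, k=st.floats(min_value=0.5, max_value=20))
@settings(max_examples=50, derandomize=True)
def test_parallel_identical_copies_closed_form(e, k):
    out = combine_parallel([e], factors=[k])
    assert out.resistance == pytest.approx(e.resistance / k, rel=1e-12)
    assert out.compliance == pytest.approx(e.compliance * k, rel=1e-12)


@given(trio=st.lists(elements, min_size=3, max_size=3))
@settings(max_examples=100, derandomize=True)
def test_associativity_both_modes(trio):
    a, b, c = trio
    flat_s = combine_series(trio)
    nested_s = combine_series([combine_series([a, b]), c])
    assert flat_s.resistance == pytest.approx(nested_s.resistance, rel=1e-12)
    assert flat_s.compliance == pytest.approx(nested_s.compliance, rel=1e-12)
    flat_p = combine_parallel(trio)
    nested_p = combine_parallel([combine_parallel([a, b]), c])
    assert flat_p.resistance == pytest.approx(nested_p.resistance, rel=1e-12)
    assert flat_p.compliance == pytest.approx(nested_p.compliance, rel=1e-12)


@given(pair=st.lists(elements, min_size=2, max_size=4))
@settings(max_examples=100, derandomize=True)
def test_bounds_and_duality(pair):
    s = combine_series(pair)
    p = combine_parallel(pair)
    assert s.resistance >= max(e.resistance for e in pair)
    assert p.resistance <= min(e.resistance for e in pair)
    assert p.compliance >= max(e.compliance for e in pair)
    assert s.compliance <= min(e.compliance for e in pair)
    # duality: swapping (R, C) and series<->parallel yields the same algebra
    swapped = [LumpedElement(e.compliance, e.resistance) for e in pair]
    dual = combine_series(swapped)
    assert dual.resistance == pytest.approx(p.compliance, rel=1e-12)
    assert dual.compliance == pytest.approx(p.resistance, rel=1e-12)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        combine_series([])
    with pytest.raises(ValueError):
        combine_parallel([])
    with pytest.raises(ValueError, match="zero compliance"):
        combine_series([LumpedElement(1e8, 0.0), LumpedElement(1e8, 1e-14)])
    with pytest.raises(ValueError, match="zero resistance"):
        combine_parallel([LumpedElement(0.0, 1e-14)])
    with pytest.raises(ValueError):
        combine_parallel([LumpedElement(1e8, 1e-14)], factors=[-1.0])


def test_single_leaf_recipe_is_identity():
    base = {"B1": LumpedElement(4.80e6, 1.48e-12)}
    table = RecipeTable((RecipeEntry("R1", ReductionNode.parallel(
        ReductionNode.leaf("B1"))),))
    out = evaluate_recipes(table, base)
    assert out["R1"] == base["B1"]


def test_recipe_chaining_and_aliases():
    base = {"A": LumpedElement(1e8, 1e-14), "B": LumpedElement(2e8, 2e-14)}
    table = RecipeTable((
        RecipeEntry("R1", ReductionNode.series(
            ReductionNode.leaf("A"), ReductionNode.leaf("B")), aliases=("C1",)),
        RecipeEntry("R2", ReductionNode.parallel(
            ReductionNode.leaf("C1", factor=2))),
    ))
    out = evaluate_recipes(table, base)
    assert out["R1"] is out["C1"]
    assert out["R2"].resistance == pytest.approx(out["R1"].resistance / 2)


def test_dangling_reference_names_offender():
    table = RecipeTable((RecipeEntry("R1", ReductionNode.series(
        ReductionNode.leaf("NOPE"))),))
    with pytest.raises(ValueError, match="R1.*NOPE"):
        evaluate_recipes(table, {"A": LumpedElement(1e8, 1e-14)})
    with pytest.raises(ValueError, match="NOPE"):
        table.validate(["A"])


def test_duplicate_recipe_names_rejected():
    node = ReductionNode.series(ReductionNode.leaf("A"))
    with pytest.raises(ValueError, match="duplicate"):
        RecipeTable((RecipeEntry("R1", node), RecipeEntry("R1", node)))


def test_leaf_compliance_factor_splits_quantities():
    base = {"A": LumpedElement(1.6e9, 1.0e-15)}
    node = ReductionNode.parallel(
        ReductionNode.leaf("A", factor=16, compliance_factor=1))
    out = evaluate_recipes(RecipeTable((RecipeEntry("R1", node),)), base)
    assert out["R1"].resistance == pytest.approx(1.0e8)
    assert out["R1"].compliance == pytest.approx(1.0e-15)


def test_compare_to_printed_reporting():
    report = compare_to_printed(
        {"R16": 6.236e7, "R19": 7.89e7, "extra": 1.0},
        {"R16": 6.24e7, "R19": 5.89e7, "missing": 2.0},
        rel_tol=0.01,
    )
    report = report.set_index("name")
    assert bool(report.loc["R16", "passed"])
    assert not bool(report.loc["R19", "passed"])
    assert report.loc["R19", "rel_error"] > 0.3
    # missing keys are reported, not fatal
    assert {"extra", "missing"} <= set(report.index)
    assert list(report.index) == sorted(report.index)
    identical = compare_to_printed({"a": 1.0}, {"a": 1.0})
    assert identical["rel_error"].iloc[0] == 0.0
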
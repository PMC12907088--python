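"""Parent/metabolite ratio computation, exclusion rules, group contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoflux.core_data import SourceGroup
from neoflux.panel import DEFAULT_PAIRING
from neoflux.pm_ratio import TOTAL_PAIR, pm_ratio_by_group, pm_ratios, ratio_summary
from tests.conftest import make_plant, make_table

PAIRING = {"P1": ("P1/M1", ["M1"])}


def _ratios(table, **kw):
    return pm_ratios(table, pairing=PAIRING, include_total=False, **kw)


def test_unit_ratio_included(two_analytes):
    table = make_table({("W1", "P1"): [10.0], ("W1", "M1"): [10.0]}, two_analytes)
    (r,) = _ratios(table)
    assert r.ratio == 1.0 and not r.excluded


def test_extreme_ratio_excluded(two_analytes):
    table = make_table({("W1", "P1"): [500.0], ("W1", "M1"): [1.0]}, two_analytes)
    (r,) = _ratios(table)
    assert r.excluded and r.ratio == 500.0


def test_zero_denominator_excluded_with_reason(two_analytes):
    table = make_table({("W1", "P1"): [5.0], ("W1", "M1"): [0.0]}, two_analytes)
    (r,) = _ratios(table)
    assert r.excluded and r.reason == "zero denominator"


def test_censored_parent_gives_zero_included(two_analytes):
    table = make_table({("W1", "P1"): [0.0], ("W1", "M1"): [4.0]}, two_analytes)
    (r,) = _ratios(table)
    assert r.ratio == 0.0 and not r.excluded


def test_multi_metabolite_denominator_is_sum(panel):
    values = {
        ("W1", "IMI"): [30.0],
        ("W1", "DN-IMI"): [10.0],
        ("W1", "5-OH-IMI"): [20.0],
        ("W1", "IMI-urea"): [30.0],
    }
    table = make_table(values, panel)
    results = pm_ratios(table, pairing={"IMI": DEFAULT_PAIRING["IMI"]}, include_total=False)
    assert results[0].ratio == pytest.approx(30.0 / 60.0)


@given(st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=50, deadline=None)
def test_scale_invariance(scale):
    from neoflux.core_data import AnalyteClass, AnalyteDef

    analytes = [
        AnalyteDef("P1", AnalyteClass.PARENT, None, lod=1e-9, loq=1e-9),
        AnalyteDef("M1", AnalyteClass.METABOLITE, "P1", lod=1e-9, loq=1e-9),
    ]
    base = make_table({("W1", "P1"): [8.0], ("W1", "M1"): [4.0]}, analytes)
    scaled = make_table({("W1", "P1"): [8.0 * scale], ("W1", "M1"): [4.0 * scale]}, analytes)
    (r0,) = pm_ratios(base, pairing=PAIRING, include_total=False)
    (r1,) = pm_ratios(scaled, pairing=PAIRING, include_total=False)
    assert r1.ratio == pytest.approx(r0.ratio, rel=1e-9)


def test_summary_applies_exclusion_before_aggregation(two_analytes):
    values = {
        ("W1", "P1"): [10.0], ("W1", "M1"): [10.0],   # ratio 1
        ("W2", "P1"): [30.0], ("W2", "M1"): [10.0],   # ratio 3
        ("W3", "P1"): [500.0], ("W3", "M1"): [1.0],   # excluded > 100
    }
    table = make_table(values, two_analytes)
    summary = ratio_summary(_ratios(table)).set_index("pair").loc["P1/M1"]
    assert summary["n_included"] == 2 and summary["n_excluded"] == 1
    assert summary["mean"] == pytest.approx(2.0)
    assert summary["sd"] == pytest.approx(np.std([1.0, 3.0], ddof=1))


def test_group_means_and_t(two_analytes):
    registry = [
        make_plant(f"A{i}", source_group=SourceGroup.G0_NONE) for i in range(3)
    ] + [make_plant(f"B{i}", source_group=SourceGroup.G1_INDUSTRIAL) for i in range(3)]
    values = {}
    for i in range(3):
        values[(f"A{i}", "P1")] = [2.0]
        values[(f"A{i}", "M1")] = [1.0]
        values[(f"B{i}", "P1")] = [12.0]
        values[(f"B{i}", "M1")] = [1.0]
    table = make_table(values, two_analytes)
    results = _ratios(table)
    means, tests = pm_ratio_by_group(results, registry, pair="P1/M1")
    by_group = means.set_index("group")["mean"]
    assert by_group["G0_NONE"] == pytest.approx(2.0)
    assert by_group["G1_INDUSTRIAL"] == pytest.approx(12.0)
    assert tests.iloc[0]["skipped"] == False  # noqa: E712


def test_group_equal_ratios_t_zero(two_analytes):
    registry = [
        make_plant("A1", source_group=SourceGroup.G0_NONE),
        make_plant("A2", source_group=SourceGroup.G0_NONE),
        make_plant("B1", source_group=SourceGroup.G2_AGRICULTURAL),
        make_plant("B2", source_group=SourceGroup.G2_AGRICULTURAL),
    ]
    values = {(p, "P1"): [6.0] for p in ("A1", "A2", "B1", "B2")}
    values.update({(p, "M1"): [3.0] for p in ("A1", "A2", "B1", "B2")})
    table = make_table(values, two_analytes)
    means, tests = pm_ratio_by_group(_ratios(table), registry, pair="P1/M1")
    assert (means["mean"] == 2.0).all()
    assert tests.iloc[0]["t"] == 0.0 and tests.iloc[0]["p"] == 1.0


def test_group_shift_detected_at_power(two_analytes):
    """Power-simulation oracle: a 6-vs-6 ratio shift of 10 with sd 1 is detected."""
    registry = [make_plant(f"A{i}", source_group=SourceGroup.G0_NONE) for i in range(6)]
    registry += [make_plant(f"B{i}", source_group=SourceGroup.G1_INDUSTRIAL) for i in range(6)]
    rng = np.random.default_rng(7)
    hits = 0
    reps = 200
    for _ in range(reps):
        values = {}
        for i in range(6):
            values[(f"A{i}", "P1")] = [max(rng.normal(12.0, 1.0), 0.1)]
            values[(f"A{i}", "M1")] = [1.0]
            values[(f"B{i}", "P1")] = [max(rng.normal(2.0, 1.0), 0.1)]
            values[(f"B{i}", "M1")] = [1.0]
        table = make_table(values, two_analytes)
        _, tests = pm_ratio_by_group(_ratios(table), registry, pair="P1/M1")
        if tests.iloc[0]["p"] < 0.05:
            hits += 1
    assert hits / reps >= 0.95


def test_total_pair_uses_class_totals(panel):
    values = {("W1", a.code): [10.0] for a in panel}
    table = make_table(values, panel)
    results = pm_ratios(table)
    total = [r for r in results if r.pair == TOTAL_PAIR]
    assert total[0].ratio == pytest.approx(80.0 / 60.0)  # 8 parents / 6 metabolites


def test_empty_metabolite_set_rejected(two_analytes):
    table = make_table({("W1", "P1"): [1.0]}, two_analytes)
    with pytest.raises(ValueError, match="empty metabolite set"):
        pm_ratios(table, pairing={"P1": ("P1/none", [])}, include_total=False)
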
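"""Detection frequencies, summaries, composition profiles, group tests, correlations."""

import numpy as np
import pytest
from scipy import stats

from neoflux.core_data import AnalyteClass, SourceGroup
from neoflux.occurrence import (
    composition_profile,
    correlate,
    correlate_with_registry,
    detection_frequency,
    detection_frequency_table,
    group_compare,
    summarize,
)
from tests.conftest import make_plant, make_table


def test_detection_frequency_counts_plants(two_analytes):
    values = {(f"W{i}", "P1"): [1.0] for i in range(12)}
    values.update({(f"W{i}", "P1"): [0.0] for i in range(12, 21)})
    values.update({(f"W{i}", "M1"): [0.5] for i in range(21)})
    table = make_table(values, two_analytes)
    assert detection_frequency(table, "M1") == 1.0
    assert detection_frequency(table, "P1") == pytest.approx(12 / 21)
    df = detection_frequency_table(table)
    assert df.set_index("analyte_code").loc["P1", "percent"] == 57
    assert df.set_index("analyte_code").loc["M1", "percent"] == 100


def test_detection_frequency_zero_and_replicate_invariance(two_analytes):
    base = {("W1", "P1"): [0.0], ("W2", "P1"): [3.0]}
    dup = {("W1", "P1"): [0.0, 0.0, 0.0], ("W2", "P1"): [3.0, 3.0]}
    t_base, t_dup = make_table(base, two_analytes), make_table(dup, two_analytes)
    assert detection_frequency(t_base, "P1") == detection_frequency(t_dup, "P1") == 0.5
    none = make_table({("W1", "P1"): [0.0]}, two_analytes)
    assert detection_frequency(none, "P1") == 0.0
    with pytest.raises(KeyError):
        detection_frequency(t_base, "XYZ")


def test_summarize_single_plant_replicates(two_analytes):
    table = make_table({("W1", "P1"): [100.0, 300.0]}, two_analytes)
    row = summarize(table, "analyte").set_index("scope").loc["P1"]
    assert row["mean"] == 200.0
    plant_rows = summarize(table, "plant").set_index("scope")
    assert plant_rows.loc["W1:PARENT", "min"] == 100.0
    assert plant_rows.loc["W1:PARENT", "max"] == 300.0


def test_summarize_class_totals_hand_arithmetic(two_analytes):
    # two plants with parent-class totals 400 and 600 -> mean 500, range [400, 600]
    table = make_table({("W1", "P1"): [400.0], ("W2", "P1"): [600.0]}, two_analytes)
    row = summarize(table, "analyte-class").set_index("scope").loc["PARENT"]
    assert row["mean"] == 500.0
    assert row["min"] == 400.0
    assert row["max"] == 600.0
    assert row["sd"] == pytest.approx(np.std([400, 600], ddof=1))


def test_summarize_all_zero(two_analytes):
    table = make_table({("W1", "P1"): [0.0], ("W2", "P1"): [0.0]}, two_analytes)
    assert summarize(table, "analyte-class").set_index("scope").loc["PARENT", "mean"] == 0.0


def test_composition_profile_sums_to_one(panel):
    registry = [make_plant("W1", district="QP"), make_plant("W2", district="JS")]
    values = {(p, a.code): [float(i + 1)] for i, a in enumerate(panel) for p in ("W1", "W2")}
    table = make_table(values, panel)
    prof = composition_profile(table, registry)
    sums = prof.groupby(["group", "analyte_class"])["abundance"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_composition_profile_degenerate_group_flagged(two_analytes):
    registry = [make_plant("W1", district="QP"), make_plant("W2", district="JS")]
    table = make_table({("W1", "P1"): [5.0], ("W2", "P1"): [0.0]}, two_analytes)
    prof = composition_profile(table, registry)
    js = prof[(prof["group"] == "JS") & (prof["analyte_class"] == "PARENT")]
    assert not js["defined"].any()
    assert not prof["abundance"].isna().any()
    qp = prof[(prof["group"] == "QP") & (prof["analyte_class"] == "PARENT")]
    assert qp["abundance"].sum() == pytest.approx(1.0)


def test_composition_equal_means_split_half(two_analytes):
    analytes = two_analytes
    registry = [make_plant("W1")]
    # one analyte per class -> abundance 1.0 each
    table = make_table({("W1", "P1"): [3.0], ("W1", "M1"): [3.0]}, analytes)
    prof = composition_profile(table, registry).set_index("analyte_code")
    assert prof.loc["P1", "abundance"] == 1.0
    assert prof.loc["M1", "abundance"] == 1.0


def test_group_compare_identical_groups(two_analytes):
    registry = [
        make_plant("W1", source_group=SourceGroup.G0_NONE),
        make_plant("W2", source_group=SourceGroup.G0_NONE),
        make_plant("W3", source_group=SourceGroup.G2_AGRICULTURAL),
        make_plant("W4", source_group=SourceGroup.G2_AGRICULTURAL),
    ]
    table = make_table({(f"W{i}", "P1"): [100.0] for i in range(1, 5)}, two_analytes)
    res = group_compare(table, registry, AnalyteClass.PARENT)
    row = res.pairwise.iloc[0]
    assert row["t"] == 0.0 and row["p"] == 1.0


def test_group_compare_skips_singleton_group(two_analytes):
    registry = [
        make_plant("W1", source_group=SourceGroup.G0_NONE),
        make_plant("W2", source_group=SourceGroup.G0_NONE),
        make_plant("W3", source_group=SourceGroup.G1_INDUSTRIAL),
    ]
    table = make_table({(f"W{i}", "P1"): [float(i * 50)] for i in range(1, 4)}, two_analytes)
    with pytest.warns(UserWarning, match="skipped"):
        res = group_compare(table, registry, AnalyteClass.PARENT)
    assert res.pairwise.iloc[0]["skipped"]


def test_group_compare_power_simulation(two_analytes):
    """Oracle: Welch t at n=6 vs n=6 with a 361 ng/L shift and sd 50 is detected
    essentially always (power simulation, 200 seeded replicates)."""
    registry = [make_plant(f"A{i}", source_group=SourceGroup.G0_NONE) for i in range(6)]
    registry += [make_plant(f"B{i}", source_group=SourceGroup.G3_BOTH) for i in range(6)]
    rng = np.random.default_rng(42)
    hits = 0
    reps = 200
    for _ in range(reps):
        values = {(f"A{i}", "P1"): [rng.normal(461, 50)] for i in range(6)}
        values.update({(f"B{i}", "P1"): [rng.normal(822, 50)] for i in range(6)})
        table = make_table({k: [max(v[0], 0.0)] for k, v in values.items()}, two_analytes)
        res = group_compare(table, registry, AnalyteClass.PARENT)
        if res.pairwise.iloc[0]["p"] < 0.05:
            hits += 1
    assert hits / reps >= 0.95


def test_correlate_exact_cases():
    x = np.arange(10.0)
    r, _ = correlate(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    # constructed orthogonal pair: y has zero covariance with x
    x2 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    y2 = np.array([1.0, -1.0, 0.0, -1.0, 1.0])
    r2, _ = correlate(x2, y2)
    assert r2 == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(correlate(np.ones(5), x2)[0])


def test_correlate_matches_textbook_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
    y = np.array([2.0, 3.0, 3.0, 8.0, 9.0])
    r, p = correlate(x, y)
    rx = x - x.mean()
    ry = y - y.mean()
    r_hand = float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    assert r == pytest.approx(r_hand, rel=1e-12)
    t = r_hand * np.sqrt(3 / (1 - r_hand**2))
    assert p == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-9)


def test_correlate_with_registry_self_consistency(two_analytes):
    registry = [make_plant(f"W{i}", served_population=1e5 + 1e4 * i) for i in range(6)]
    values = {
        (r.wwtp_id, "P1"): [0.001 * r.served_population] for r in registry
    }
    table = make_table(values, two_analytes)
    df = correlate_with_registry(table, registry, fields=("served_population",))
    parent = df[df["analyte_class"] == "PARENT"].iloc[0]
    assert parent["r"] == pytest.approx(1.0)
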
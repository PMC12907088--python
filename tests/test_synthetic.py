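"""Generator determinism, declared ranges, and ground-truth recovery."""

import numpy as np
import pytest

from neoflux.core_data import AnalyteClass, SourceGroup
from neoflux.extrapolation import fit_with_pruning
from neoflux.removal import build_rr_matrix, entry_value
from neoflux.synthetic import (
    CAPACITY_RANGE_KT_A,
    default_truth,
    generate_concentrations,
    generate_literature_rr,
    generate_registry,
    noise_free_truth,
    read_truth_json,
    write_truth_json,
)


def test_registry_deterministic_and_in_range():
    a = generate_registry(21, seed=1)
    b = generate_registry(21, seed=1)
    assert a == b
    lo, hi = CAPACITY_RANGE_KT_A
    for rec in a:
        assert lo <= rec.designed_capacity <= hi
        assert rec.served_population > 0 and rec.discharge_volume > 0
    assert generate_registry(21, seed=2) != a


def test_registry_rejects_single_plant():
    with pytest.raises(ValueError):
        generate_registry(1, seed=1)


def test_concentrations_deterministic(panel):
    reg = generate_registry(6, seed=4)
    truth = default_truth(panel)
    t1 = generate_concentrations(reg, truth, 3, seed=9, analytes=panel)
    t2 = generate_concentrations(reg, truth, 3, seed=9, analytes=panel)
    assert t1.frame.equals(t2.frame)
    with pytest.raises(ValueError):
        generate_concentrations(reg, truth, 0, seed=9, analytes=panel)


def test_noise_free_concentrations_exactly_linear(panel):
    """With all noise off, every analyte is an exact affine function of population."""
    reg = generate_registry(8, seed=5)
    truth = noise_free_truth(panel)
    table = generate_concentrations(reg, truth, 2, seed=5, analytes=panel)
    means = table.plant_means()
    pops = {r.wwtp_id: r.served_population for r in reg}
    for a in panel:
        for plant in means.index:
            expected = truth.slope[a.code] * pops[plant] + truth.intercept[a.code]
            assert means.loc[plant, a.code] == pytest.approx(expected, rel=1e-12)


def test_group_effect_raises_group_mean(panel):
    """Construction check: a positive G2 offset lifts the expected G2 parent mean."""
    reg = generate_registry(30, seed=11)
    truth = noise_free_truth(panel)
    truth.group_effects[AnalyteClass.PARENT.value][SourceGroup.G2_AGRICULTURAL.value] = 300.0
    table = generate_concentrations(reg, truth, 1, seed=11, analytes=panel)
    totals = table.class_totals(AnalyteClass.PARENT)
    pops = {r.wwtp_id: r.served_population for r in reg}
    slope = truth.class_slope(panel, AnalyteClass.PARENT)
    intercept = truth.class_intercept(panel, AnalyteClass.PARENT)
    group_of = {r.wwtp_id: r.source_group for r in reg}
    resid = {p: totals[p] - slope * pops[p] - intercept for p in totals.index}
    g2 = [resid[p] for p in resid if group_of[p] is SourceGroup.G2_AGRICULTURAL]
    g0 = [resid[p] for p in resid if group_of[p] is SourceGroup.G0_NONE]
    assert np.mean(g2) > np.mean(g0)
    assert np.mean(g2) == pytest.approx(300.0, rel=1e-9)


def test_regression_recovers_truth_on_noise_free_data(panel):
    """Oracle: closed-form least squares on exact affine data returns the truth."""
    reg = generate_registry(21, seed=6)
    truth = noise_free_truth(panel)
    table = generate_concentrations(reg, truth, 2, seed=6, analytes=panel)
    totals = table.class_totals(AnalyteClass.PARENT)
    points = [(r.wwtp_id, r.served_population, totals[r.wwtp_id]) for r in reg]
    fit = fit_with_pruning(points, target_r2=0.95)
    assert fit.slope == pytest.approx(truth.class_slope(panel, AnalyteClass.PARENT), rel=1e-9)
    assert fit.intercept == pytest.approx(truth.class_intercept(panel, AnalyteClass.PARENT), rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.excluded_ids == []


def test_literature_zero_spread_recovers_truth_exactly(panel):
    truth = default_truth(panel)
    entries = generate_literature_rr(truth, n_entries_per_cell=3, spread=0.0, seed=2)
    for e in entries:
        assert entry_value(e) == truth.true_rr[(e.process_class, e.analyte_code)]
    reg = [r for r in generate_registry(10, seed=2) if not r.has_uv]
    matrix = build_rr_matrix(reg, entries, panel)
    for rec in reg:
        for a in panel:
            parent = a.parent_code or a.code
            assert matrix.rr.loc[rec.wwtp_id, a.code] == pytest.approx(
                truth.true_rr[(rec.process_class.value, parent)], abs=1e-12
            )


def test_literature_deterministic_and_validated(panel):
    truth = default_truth(panel)
    a = generate_literature_rr(truth, spread=0.05, seed=3)
    b = generate_literature_rr(truth, spread=0.05, seed=3)
    assert a == b
    with pytest.raises(ValueError):
        generate_literature_rr(truth, spread=-0.1, seed=3)


def test_aggregated_rr_concentrates_with_entries(panel):
    """Monte-Carlo oracle: the aggregation error shrinks like spread/sqrt(n)."""
    truth = default_truth(panel)
    cell = ("AAO_LIKE", "IMI")
    spread = 0.12
    for n_entries, budget in [(2, 0.35), (16, 0.12)]:
        errs = []
        for seed in range(300):
            entries = [
                e for e in generate_literature_rr(truth, n_entries, spread, seed)
                if (e.process_class, e.analyte_code) == cell
            ]
            agg = np.mean([entry_value(e) for e in entries])
            errs.append(abs(agg - truth.true_rr[cell]))
        # mean |error| of a mean of n uniforms on +/-spread: ~spread/sqrt(n)
        assert np.mean(errs) < budget * spread


def test_truth_json_roundtrip(tmp_path, panel):
    truth = default_truth(panel)
    path = tmp_path / "truth.json"
    write_truth_json(truth, path)
    back = read_truth_json(path)
    assert back.slope == truth.slope
    assert back.true_rr == truth.true_rr
    assert back.replicate_cv == truth.replicate_cv
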
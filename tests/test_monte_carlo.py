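"""Monte-Carlo propagation: determinism, degeneracy, analytic expectations."""

import numpy as np
import pandas as pd
import pytest

from neoflux.emission import point_emission
from neoflux.monte_carlo import (
    PlantClassInput,
    UncertaintyConfig,
    run_mc,
    variance_attribution,
)


def _cell(wwtp_id="W1", conc_mean=500.0, conc_sd=0.0, rr_mean=0.4, rr_low=0.4,
          rr_high=0.4, volume=1000.0, region="QP", analyte_class="PARENT"):
    return PlantClassInput(
        wwtp_id=wwtp_id, analyte_class=analyte_class, conc_mean=conc_mean,
        conc_sd=conc_sd, rr_mean=rr_mean, rr_low=rr_low, rr_high=rr_high,
        volume=volume, region=region,
    )


def _degenerate_config(n=5000, seed=0):
    return UncertaintyConfig(n_iterations=n, seed=seed, flow_cv=0.0, analytical_cv=0.0)


def test_degenerate_collapses_to_deterministic():
    inputs = [_cell("W1", conc_mean=500.0), _cell("W2", conc_mean=800.0, volume=300.0)]
    result = run_mc(inputs, _degenerate_config())
    expected = point_emission(500.0, 0.4, 1000.0) + point_emission(800.0, 0.4, 300.0)
    total = result.per_region.set_index(["region", "analyte_class"]).loc[("ALL", "PARENT")]
    assert total["mean"] == pytest.approx(expected, rel=1e-12)
    assert total["sd"] == pytest.approx(0.0, abs=1e-9)
    assert total["ci_lower"] == pytest.approx(total["ci_upper"], rel=1e-12)


def test_same_seed_bit_identical_and_order_invariant():
    inputs = [
        _cell("W1", conc_sd=50.0, rr_low=0.3, rr_high=0.5),
        _cell("W2", conc_mean=900.0, conc_sd=90.0, rr_low=0.2, rr_high=0.6, region="JS"),
    ]
    config = UncertaintyConfig(n_iterations=4000, seed=7)
    r1 = run_mc(inputs, config)
    r2 = run_mc(inputs, config)
    pd.testing.assert_frame_equal(r1.per_plant, r2.per_plant)
    pd.testing.assert_frame_equal(r1.per_region, r2.per_region)
    # per-plant summaries do not depend on registry ordering
    r3 = run_mc(list(reversed(inputs)), config)
    m1 = r1.per_plant.set_index("wwtp_id").sort_index()
    m3 = r3.per_plant.set_index("wwtp_id").sort_index()
    pd.testing.assert_frame_equal(m1, m3)


def test_different_seed_differs():
    inputs = [_cell(conc_sd=50.0)]
    a = run_mc(inputs, UncertaintyConfig(n_iterations=2000, seed=1))
    b = run_mc(inputs, UncertaintyConfig(n_iterations=2000, seed=2))
    assert a.per_plant.loc[0, "mean"] != b.per_plant.loc[0, "mean"]


def test_mc_mean_matches_analytic_expectation():
    """Oracle: under independence E[E] = E[C]*E[A]*E[1-RR]*E[V-mult]*V*const;
    with spreads small enough that truncation never binds, the 10^5-iteration
    mean lands within 1%."""
    inp = _cell(conc_mean=500.0, conc_sd=25.0, rr_mean=0.4, rr_low=0.3, rr_high=0.5)
    config = UncertaintyConfig(n_iterations=100_000, seed=3, flow_cv=0.05, analytical_cv=0.05)
    result = run_mc([inp], config)
    analytic = 500.0 * 1.0 * (1 - 0.4) * 1.0 * 1000.0 * 1e7 * 1e-12
    assert result.per_plant.loc[0, "mean"] == pytest.approx(analytic, rel=0.01)


def test_all_draws_nonnegative_under_heavy_spread():
    inp = _cell(conc_mean=10.0, conc_sd=200.0, rr_low=0.0, rr_high=1.0)
    config = UncertaintyConfig(n_iterations=20_000, seed=5, flow_cv=1.0, analytical_cv=1.0)
    result = run_mc([inp], config)
    assert result.per_plant.loc[0, "ci_lower"] >= 0.0
    assert result.per_region["ci_lower"].min() >= 0.0


def test_regional_sd_bounded_by_sum_of_plant_sds():
    inputs = [
        _cell("W1", conc_sd=60.0, rr_low=0.2, rr_high=0.6),
        _cell("W2", conc_mean=700.0, conc_sd=80.0, rr_low=0.3, rr_high=0.5, region="QP"),
    ]
    config = UncertaintyConfig(n_iterations=30_000, seed=9)
    result = run_mc(inputs, config)
    total_sd = result.per_region.set_index(["region", "analyte_class"]).loc[("ALL", "PARENT"), "sd"]
    assert total_sd <= result.per_plant["sd"].sum() + 1e-12


def test_halving_iterations_stable_mean():
    inp = _cell(conc_mean=500.0, conc_sd=50.0, rr_low=0.3, rr_high=0.5)
    full = run_mc([inp], UncertaintyConfig(n_iterations=40_000, seed=13))
    half = run_mc([inp], UncertaintyConfig(n_iterations=20_000, seed=13))
    sd = full.per_plant.loc[0, "sd"]
    se = 3 * sd / np.sqrt(20_000)
    assert abs(full.per_plant.loc[0, "mean"] - half.per_plant.loc[0, "mean"]) < se


def test_variance_attribution_single_source():
    inp = _cell(conc_mean=500.0, conc_sd=50.0)  # only concentration varies
    att = variance_attribution([inp], _degenerate_config(n=20_000))
    att = att.set_index("source")
    assert att.loc["concentration", "fraction"] == pytest.approx(1.0)
    assert att.loc["removal", "fraction"] == pytest.approx(0.0, abs=1e-12)


def test_variance_attribution_degenerate_flagged():
    att = variance_attribution([_cell()], _degenerate_config(n=1000))
    assert att["degenerate"].all()
    assert att["fraction"].isna().all()


def test_variance_attribution_equal_sources_balanced():
    """Variance-algebra oracle: two multiplicative sources built with equal
    relative variance receive equal attribution within MC error."""
    cv = 0.08
    inp = _cell(conc_mean=500.0, conc_sd=cv * 500.0)
    config = UncertaintyConfig(n_iterations=100_000, seed=21, flow_cv=cv, analytical_cv=0.0)
    att = variance_attribution([inp], config).set_index("source")
    assert att.loc["concentration", "fraction"] == pytest.approx(0.5, abs=0.03)
    assert att.loc["flow", "fraction"] == pytest.approx(0.5, abs=0.03)


def test_run_mc_input_validation():
    with pytest.raises(ValueError):
        run_mc([], _degenerate_config())
    with pytest.raises(ValueError):
        run_mc([_cell(), _cell()], _degenerate_config())
    with pytest.raises(ValueError):
        UncertaintyConfig(n_iterations=0)
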
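"""Monte-Carlo propagation of the four emission uncertainty sources.

Per iteration and per (plant, class) the mass balance is evaluated with

  - concentration: Normal(mean, sd) truncated at 0 — sd is the regression
    prediction sd for extrapolated plants or the standard error of the
    measured mean for sampled plants;
  - removal rate: Uniform(low, high) over the plant's literature entry-value
    bounds, clipped to [0, 1];
  - flow: multiplicative Normal(1, flow_cv), truncated at 0 (design-flow
    error);
  - analytical: multiplicative Normal(1, analytical_cv), truncated at 0
    (method-recovery uncertainty on the concentration).

Sources are sampled independently; each plant draws from its own substream
derived from the root seed and the plant id, so results are invariant to
registry ordering and fully reproducible. Summaries are the empirical mean,
sd and percentile confidence interval over iterations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["UncertaintyConfig", "PlantClassInput", "MCResult", "run_mc", "variance_attribution"]

_KG_PER_NG = 1e-12
_L_PER_VOLUME_UNIT = 1e7

SOURCES = ("concentration", "removal", "flow", "analytical")


@dataclass(frozen=True)
class UncertaintyConfig:
    """Monte-Carlo settings; all spreads are overridable, defaults declared.

    flow_cv and analytical_cv are relative standard deviations of the
    multiplicative error terms; ci_level sets the empirical percentile
    interval (0.95 -> 2.5/97.5).
    """

    n_iterations: int = 100_000
    seed: int = 0
    flow_cv: float = 0.10
    analytical_cv: float = 0.125
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.flow_cv < 0 or self.analytical_cv < 0:
            raise ValueError("cv values must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class PlantClassInput:
    """Inputs for one (plant, analyte class) cell of the MC emission model."""

    wwtp_id: str
    analyte_class: str
    conc_mean: float  # ng/L
    conc_sd: float  # ng/L
    rr_mean: float  # fraction
    rr_low: float
    rr_high: float
    volume: float  # 10^7 L/a
    region: str = ""

    def __post_init__(self) -> None:
        if self.conc_mean < 0 or self.conc_sd < 0:
            raise ValueError(f"{self.wwtp_id}: concentration mean/sd must be >= 0")
        if not (0 <= self.rr_low <= self.rr_high <= 1) or not 0 <= self.rr_mean <= 1:
            raise ValueError(f"{self.wwtp_id}: removal fractions must satisfy 0<=low<=high<=1")
        if self.volume <= 0:
            raise ValueError(f"{self.wwtp_id}: volume must be > 0")


@dataclass
class MCResult:
    per_plant: pd.DataFrame  # wwtp_id, analyte_class, region, mean, sd, ci_lower, ci_upper
    per_region: pd.DataFrame  # region ('ALL' = grand total), analyte_class, mean, sd, ci_lower, ci_upper


def _plant_rng(seed: int, wwtp_id: str, analyte_class: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{wwtp_id}|{analyte_class}".encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _draw_emissions(inp: PlantClassInput, config: UncertaintyConfig,
                    active: Sequence[str] = SOURCES) -> np.ndarray:
    """Emission draws (kg/a) for one cell; inactive sources are degenerate."""
    n = config.n_iterations
    rng = _plant_rng(config.seed, inp.wwtp_id, inp.analyte_class)
    # draw in fixed source order so substreams stay aligned across configs
    if "concentration" in active and inp.conc_sd > 0:
        conc = np.maximum(rng.normal(inp.conc_mean, inp.conc_sd, n), 0.0)
    else:
        rng.normal(size=n)
        conc = np.full(n, inp.conc_mean)
    if "removal" in active and inp.rr_high > inp.rr_low:
        rr = np.clip(rng.uniform(inp.rr_low, inp.rr_high, n), 0.0, 1.0)
    else:
        rng.uniform(size=n)
        rr = np.full(n, inp.rr_mean)
    if "flow" in active and config.flow_cv > 0:
        flow = np.maximum(rng.normal(1.0, config.flow_cv, n), 0.0)
    else:
        rng.normal(size=n)
        flow = np.ones(n)
    if "analytical" in active and config.analytical_cv > 0:
        ana = np.maximum(rng.normal(1.0, config.analytical_cv, n), 0.0)
    else:
        rng.normal(size=n)
        ana = np.ones(n)
    return conc * ana * (1.0 - rr) * inp.volume * flow * _L_PER_VOLUME_UNIT * _KG_PER_NG


def _summary(draws: np.ndarray, ci_level: float) -> dict[str, float]:
    lo = 100 * (1 - ci_level) / 2
    return {
        "mean": float(np.mean(draws)),
        "sd": float(np.std(draws, ddof=0)),
        "ci_lower": float(np.percentile(draws, lo)),
        "ci_upper": float(np.percentile(draws, 100 - lo)),
    }


def run_mc(inputs: Sequence[PlantClassInput], config: UncertaintyConfig) -> MCResult:
    """Propagate all four uncertainty sources through the emission model.

    Returns per-plant and per-region/total summaries (mean, sd, percentile
    CI in kg/a). Regional draws are iteration-wise sums of the independent
    per-plant draws.
    """
    if not inputs:
        raise ValueError("no Monte-Carlo inputs")
    ids = [(i.wwtp_id, i.analyte_class) for i in inputs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate (plant, class) cells in MC inputs")
    plant_rows = []
    totals: dict[tuple[str, str], np.ndarray] = {}
    for inp in inputs:
        draws = _draw_emissions(inp, config)
        plant_rows.append(
            {"wwtp_id": inp.wwtp_id, "analyte_class": inp.analyte_class,
             "region": inp.region, **_summary(draws, config.ci_level)}
        )
        for region_key in (inp.region, "ALL"):
            key = (region_key, inp.analyte_class)
            if key in totals:
                totals[key] = totals[key] + draws
            else:
                totals[key] = draws.copy()
    region_rows = [
        {"region": region, "analyte_class": cls, **_summary(draws, config.ci_level)}
        for (region, cls), draws in sorted(totals.items())
    ]
    return MCResult(per_plant=pd.DataFrame(plant_rows), per_region=pd.DataFrame(region_rows))


def variance_attribution(
    inputs: Sequence[PlantClassInput],
    config: UncertaintyConfig,
    analyte_class: str | None = None,
) -> pd.DataFrame:
    """Fraction of total-emission variance attributable to each source.

    One-at-a-time re-runs: each source active alone with the others held at
    their central values; fractions are each run's total variance divided by
    the sum over sources. A zero total is flagged degenerate.
    """
    use = [i for i in inputs if analyte_class is None or i.analyte_class == analyte_class]
    if not use:
        raise ValueError("no MC inputs match the requested class")
    variances = {}
    for source in SOURCES:
        total = None
        for inp in use:
            draws = _draw_emissions(inp, config, active=(source,))
            total = draws if total is None else total + draws
        variances[source] = float(np.var(total))
    total_var = sum(variances.values())
    degenerate = total_var == 0
    rows = [
        {
            "source": s,
            "variance": v,
            "fraction": (v / total_var) if not degenerate else float("nan"),
            "degenerate": degenerate,
        }
        for s, v in variances.items()
    ]
    return pd.DataFrame(rows)
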
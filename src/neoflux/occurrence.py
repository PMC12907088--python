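"""Censoring-aware occurrence statistics for WWTP influent monitoring data.

Plant-level value of an analyte = mean over its replicates; a class total is
the per-plant sum of member-analyte plant means. All cross-plant statistics
(detection frequencies, summaries, group comparisons, correlations) operate
on those plant-level values. Group comparisons use Welch's unequal-variance
t-test; significance is conventionally read at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AnalyteClass, ConcentrationTable, WWTPRecord

__all__ = [
    "detection_frequency",
    "detection_frequency_table",
    "summarize",
    "composition_profile",
    "group_compare",
    "correlate",
    "correlate_with_registry",
]


def detection_frequency(table: ConcentrationTable, analyte: str) -> float:
    """Fraction of plants with at least one replicate > 0 for the analyte."""
    if analyte not in table.analytes:
        raise KeyError(f"unknown analyte {analyte!r}")
    df = table.frame
    sub = df[df["analyte_code"] == analyte]
    plants = df["wwtp_id"].unique()
    if len(plants) == 0:
        raise ValueError("empty concentration table")
    detected = sub[sub["value_ng_L"] > 0]["wwtp_id"].nunique()
    return detected / len(plants)


def detection_frequency_table(table: ConcentrationTable) -> pd.DataFrame:
    """Detection frequency per analyte, as fraction and integer-rounded percent."""
    rows = []
    for code in table.analytes:
        f = detection_frequency(table, code)
        rows.append({"analyte_code": code, "fraction": f, "percent": int(round(100 * f))})
    return pd.DataFrame(rows)


def summarize(table: ConcentrationTable, scope: str = "analyte-class") -> pd.DataFrame:
    """{mean, min, max, sd} of concentrations (ng/L) at the requested scope.

    - ``analyte``: statistics over plant means, per analyte;
    - ``analyte-class``: statistics over per-plant class totals;
    - ``plant``: statistics over per-replicate class totals, per plant.
    """
    means = table.plant_means()
    if means.empty:
        raise ValueError("empty concentration table")
    if scope == "analyte":
        rows = [
            {"scope": code, "mean": means[code].mean(), "min": means[code].min(),
             "max": means[code].max(), "sd": means[code].std(ddof=1) if len(means) > 1 else 0.0}
            for code in table.analytes
        ]
    elif scope == "analyte-class":
        rows = []
        for cls in AnalyteClass:
            totals = table.class_totals(cls)
            rows.append(
                {"scope": cls.value, "mean": totals.mean(), "min": totals.min(),
                 "max": totals.max(), "sd": totals.std(ddof=1) if len(totals) > 1 else 0.0}
            )
    elif scope == "plant":
        rows = []
        df = table.frame
        for cls in AnalyteClass:
            codes = table.codes(cls)
            sub = df[df["analyte_code"].isin(codes)]
            rep_totals = sub.groupby(["wwtp_id", "replicate_id"])["value_ng_L"].sum()
            for plant, vals in rep_totals.groupby(level=0):
                rows.append(
                    {"scope": f"{plant}:{cls.value}", "mean": vals.mean(), "min": vals.min(),
                     "max": vals.max(), "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0}
                )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.DataFrame(rows)


def composition_profile(
    table: ConcentrationTable,
    registry: Sequence[WWTPRecord],
    grouping: str = "district",
) -> pd.DataFrame:
    """Relative analyte abundance within each (group, analyte class).

    Abundances sum to 1 within a defined (group, class); a group whose class
    total is zero is reported with ``defined=False`` and zero abundances
    rather than NaN.
    """
    if grouping not in ("district", "source_group"):
        raise ValueError(f"unknown grouping {grouping!r}")
    key = {
        r.wwtp_id: (r.district if grouping == "district" else r.source_group.value)
        for r in registry
    }
    means = table.plant_means()
    rows = []
    groups = sorted(set(key.get(p) for p in means.index if key.get(p) is not None))
    for g in groups:
        plants = [p for p in means.index if key.get(p) == g]
        sub = means.loc[plants]
        for cls in AnalyteClass:
            codes = table.codes(cls)
            level = sub[codes].mean(axis=0)  # mean over plants of plant means
            total = level.sum()
            defined = total > 0
            for code in codes:
                rows.append(
                    {
                        "group": g,
                        "analyte_class": cls.value,
                        "analyte_code": code,
                        "abundance": (level[code] / total) if defined else 0.0,
                        "defined": bool(defined),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    group_means: pd.DataFrame
    pairwise: pd.DataFrame


def group_compare(
    table: ConcentrationTable,
    registry: Sequence[WWTPRecord],
    analyte_class: AnalyteClass,
) -> GroupComparison:
    """Per-group mean class totals and pairwise Welch two-tailed t-tests.

    Pairs involving a group with fewer than 2 plants are skipped with a
    warning (the t statistic is undefined there).
    """
    totals = table.class_totals(analyte_class)
    group_of = {r.wwtp_id: r.source_group.value for r in registry}
    df = pd.DataFrame({"total": totals})
    df["group"] = [group_of.get(p) for p in df.index]
    df = df.dropna(subset=["group"])
    means = df.groupby("group")["total"].agg(["mean", "std", "count"]).reset_index()

    groups = sorted(df["group"].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            xa = df.loc[df["group"] == ga, "total"].to_numpy()
            xb = df.loc[df["group"] == gb, "total"].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(f"group pair ({ga}, {gb}) skipped: fewer than 2 plants in a group")
                rows.append({"group_a": ga, "group_b": gb, "t": np.nan, "p": np.nan, "skipped": True})
                continue
            if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) and np.isclose(xa[0], xb[0]):
                # identical constant samples: no difference by construction
                rows.append({"group_a": ga, "group_b": gb, "t": 0.0, "p": 1.0, "skipped": False})
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"group_a": ga, "group_b": gb, "t": float(t), "p": float(p), "skipped": False})
    return GroupComparison(group_means=means, pairwise=pd.DataFrame(rows))


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p; (nan, nan) if either side has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_with_registry(
    table: ConcentrationTable,
    registry: Sequence[WWTPRecord],
    fields: Sequence[str] = ("designed_capacity", "served_population", "service_area"),
) -> pd.DataFrame:
    """Pearson correlations of per-plant class totals with registry covariates."""
    by_id = {r.wwtp_id: r for r in registry}
    rows = []
    for cls in AnalyteClass:
        totals = table.class_totals(cls)
        plants = [p for p in totals.index if p in by_id]
        y = totals.loc[plants].to_numpy()
        for field in fields:
            x = np.array([getattr(by_id[p], field) for p in plants], dtype=float)
            r, p_val = correlate(x, y)
            rows.append({"analyte_class": cls.value, "covariate": field, "r": r, "p": p_val})
    return pd.DataFrame(rows)
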
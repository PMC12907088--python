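"""Parent-to-metabolite transformation ratios.

The ratio of a parent compound's plant mean to the summed plant means of its
metabolite set is a proxy for how far transformation has proceeded before
the wastewater reaches the plant: low ratios mean extensive pre-plant
degradation. Extreme outliers (ratio > 100) and zero denominators are
excluded from every aggregate, with the reason logged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AnalyteClass, ConcentrationTable, WWTPRecord
from .panel import DEFAULT_PAIRING

__all__ = ["RatioResult", "pm_ratios", "ratio_summary", "pm_ratio_by_group", "TOTAL_PAIR"]

# label of the all-compounds ratio: total parents / total metabolites per plant
TOTAL_PAIR = "TOTAL p/m"

EXCLUDE_ABOVE = 100.0


@dataclass(frozen=True)
class RatioResult:
    """One plant's ratio for one parent/metabolite-set pair."""

    wwtp_id: str
    pair: str
    ratio: float
    excluded: bool
    reason: str | None = None


def _one_ratio(wwtp_id: str, pair: str, parent_val: float, metab_val: float,
               exclude_above: float) -> RatioResult:
    if metab_val == 0:
        return RatioResult(wwtp_id, pair, float("nan"), True, "zero denominator")
    ratio = parent_val / metab_val
    if ratio > exclude_above:
        return RatioResult(wwtp_id, pair, ratio, True, f"> {exclude_above:g}")
    return RatioResult(wwtp_id, pair, ratio, False)


def pm_ratios(
    table: ConcentrationTable,
    pairing: Mapping[str, tuple[str, Sequence[str]]] | None = None,
    exclude_above: float = EXCLUDE_ABOVE,
    include_total: bool = True,
) -> list[RatioResult]:
    """Per-plant ratios for each pair, plus the all-compounds total ratio.

    ratio = parent plant mean / sum of metabolite plant means (mass-consistent
    aggregation of multi-metabolite sets). A fully censored parent over a
    positive denominator yields ratio 0 (included); exclusion applies for
    ratio > ``exclude_above`` or a zero denominator.
    """
    pairing = dict(pairing) if pairing is not None else dict(DEFAULT_PAIRING)
    means = table.plant_means()
    results: list[RatioResult] = []
    for parent, (label, metabolites) in pairing.items():
        if parent not in table.analytes:
            raise KeyError(f"pairing references unknown parent {parent!r}")
        metabolites = list(metabolites)
        if not metabolites:
            raise ValueError(f"pair {label!r}: empty metabolite set")
        for m in metabolites:
            if m not in table.analytes:
                raise KeyError(f"pairing references unknown metabolite {m!r}")
        for plant in means.index:
            results.append(
                _one_ratio(
                    plant, label, means.loc[plant, parent],
                    means.loc[plant, metabolites].sum(), exclude_above,
                )
            )
    if include_total:
        p_total = table.class_totals(AnalyteClass.PARENT)
        m_total = table.class_totals(AnalyteClass.METABOLITE)
        for plant in means.index:
            results.append(
                _one_ratio(plant, TOTAL_PAIR, p_total[plant], m_total[plant], exclude_above)
            )
    return results


def ratio_summary(results: Sequence[RatioResult]) -> pd.DataFrame:
    """Mean +/- sd of included ratios per pair."""
    rows = []
    for pair in sorted({r.pair for r in results}):
        vals = [r.ratio for r in results if r.pair == pair and not r.excluded]
        n_excl = sum(1 for r in results if r.pair == pair and r.excluded)
        rows.append(
            {
                "pair": pair,
                "n_included": len(vals),
                "n_excluded": n_excl,
                "mean": float(np.mean(vals)) if vals else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def pm_ratio_by_group(
    results: Sequence[RatioResult],
    registry: Sequence[WWTPRecord],
    pair: str = TOTAL_PAIR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means of included ratios for one pair plus pairwise Welch t-tests."""
    group_of = {r.wwtp_id: r.source_group.value for r in registry}
    vals: dict[str, list[float]] = {}
    for r in results:
        if r.pair != pair or r.excluded or r.wwtp_id not in group_of:
            continue
        vals.setdefault(group_of[r.wwtp_id], []).append(r.ratio)
    means = pd.DataFrame(
        [
            {"group": g, "mean": float(np.mean(v)),
             "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0, "n": len(v)}
            for g, v in sorted(vals.items())
        ]
    )
    rows = []
    groups = sorted(vals)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            xa, xb = np.asarray(vals[ga]), np.asarray(vals[gb])
            if len(xa) < 2 or len(xb) < 2:
                rows.append({"group_a": ga, "group_b": gb, "t": np.nan, "p": np.nan, "skipped": True})
                continue
            if np.allclose(xa, xa[0]) and np.allclose(xb, xb[0]) and np.isclose(xa[0], xb[0]):
                rows.append({"group_a": ga, "group_b": gb, "t": 0.0, "p": 1.0, "skipped": False})
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"group_a": ga, "group_b": gb, "t": float(t), "p": float(p), "skipped": False})
    return means, pd.DataFrame(rows)


def ratios_to_frame(results: Sequence[RatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wwtp_id": [r.wwtp_id for r in results],
            "pair": [r.pair for r in results],
            "ratio": [r.ratio for r in results],
            "excluded": [r.excluded for r in results],
            "reason": [r.reason or "" for r in results],
        }
    )
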
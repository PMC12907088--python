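"""Deterministic point-source emission mass balance and derived accounting.

For plant i and compound class j the annual effluent emission is

    E_ij = C_ij * (1 - RR_i) * V_i

with C the influent concentration (ng/L), RR the plant's removal fraction and
V the annual discharge volume in units of 10^7 L; the ng -> kg conversion
gives kg/a = C * V * 10^7 / 10^12. Influent and effluent volumes are treated
as equal (one V per plant). Derived quantities: influent loads, removed mass
(load - emission), removal percentages and per-plant emission shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EmissionEstimate", "annual_load", "point_emission", "aggregate"]

_KG_PER_NG = 1e-12
_L_PER_VOLUME_UNIT = 1e7


def annual_load(conc: float, volume: float) -> float:
    """Annual influent mass (kg/a) from concentration (ng/L) and volume (10^7 L/a)."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return conc * volume * _L_PER_VOLUME_UNIT * _KG_PER_NG


def point_emission(conc: float, rr: float, volume: float) -> float:
    """Annual effluent emission (kg/a): load times the fraction not removed."""
    if not 0 <= rr <= 1:
        raise ValueError(f"removal fraction must be in [0, 1], got {rr}")
    return annual_load(conc, volume) * (1.0 - rr)


@dataclass(frozen=True)
class EmissionEstimate:
    """Per-plant, per-class annual mass balance (kg/a)."""

    wwtp_id: str
    analyte_class: str
    influent_load: float
    effluent_emission: float
    region: str = ""

    def __post_init__(self) -> None:
        if self.influent_load < 0:
            raise ValueError("influent_load must be >= 0")
        if not 0 <= self.effluent_emission <= self.influent_load + 1e-12:
            raise ValueError(
                f"effluent_emission must lie in [0, influent_load]: "
                f"{self.effluent_emission} vs {self.influent_load}"
            )

    @property
    def removed_mass(self) -> float:
        return self.influent_load - self.effluent_emission

    @property
    def removal_pct(self) -> float:
        if self.influent_load == 0:
            return float("nan")
        return 100.0 * self.removed_mass / self.influent_load


def aggregate(
    estimates: Sequence[EmissionEstimate],
    by: str = "class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Totals and per-plant shares from a collection of emission estimates.

    Returns (totals, shares): totals has one row per group (class, plant or
    region) with summed load, emission, removed mass and the removal
    percentage 100*(sum load - sum emission)/sum load; shares gives each
    plant's percent of its class's total emission. Full precision is kept;
    rounding is left to report writers.
    """
    if not estimates:
        raise ValueError("no emission estimates to aggregate")
    if by not in ("class", "plant", "region"):
        raise ValueError(f"unknown aggregation key {by!r}")
    df = pd.DataFrame(
        {
            "wwtp_id": [e.wwtp_id for e in estimates],
            "analyte_class": [e.analyte_class for e in estimates],
            "region": [e.region for e in estimates],
            "influent_load": [e.influent_load for e in estimates],
            "effluent_emission": [e.effluent_emission for e in estimates],
        }
    )
    key = {"class": "analyte_class", "plant": "wwtp_id", "region": "region"}[by]
    g = df.groupby(key)[["influent_load", "effluent_emission"]].sum()
    totals = g.reset_index().rename(columns={key: "group"})
    totals["removed_mass"] = totals["influent_load"] - totals["effluent_emission"]
    with np.errstate(invalid="ignore", divide="ignore"):
        totals["removal_pct"] = 100.0 * totals["removed_mass"] / totals["influent_load"]

    class_emission = df.groupby("analyte_class")["effluent_emission"].sum()
    shares = df.groupby(["wwtp_id", "analyte_class"])["effluent_emission"].sum().reset_index()
    shares["share_pct"] = [
        100.0 * row.effluent_emission / class_emission[row.analyte_class]
        if class_emission[row.analyte_class] > 0 else float("nan")
        for row in shares.itertuples()
    ]
    return totals, shares


def estimates_to_frame(estimates: Sequence[EmissionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wwtp_id": [e.wwtp_id for e in estimates],
            "analyte_class": [e.analyte_class for e in estimates],
            "region": [e.region for e in estimates],
            "influent_load_kg_a": [e.influent_load for e in estimates],
            "effluent_emission_kg_a": [e.effluent_emission for e in estimates],
            "removed_kg_a": [e.removed_mass for e in estimates],
            "removal_pct": [e.removal_pct for e in estimates],
        }
    )
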
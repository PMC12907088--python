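"""Risk-quotient screening: RQ = MEC / PNEC with four-band classification.

Bands (disjoint): negligible RQ <= 0.1; low 0.1 < RQ < 1; moderate
1 <= RQ < 10; high RQ >= 10. Analytes without an established PNEC are
reported as not evaluable rather than assigned a band.
"""

from __future__ import annotations

import enum
from typing import Sequence

import pandas as pd

from .core_data import AnalyteDef, ConcentrationTable

__all__ = ["RiskBand", "risk_quotient", "classify_rq", "rq_table"]


class RiskBand(str, enum.Enum):
    NEGLIGIBLE = "NEGLIGIBLE"
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


def risk_quotient(mec: float, pnec: float) -> float:
    """Exact quotient of measured environmental concentration over PNEC (ng/L each)."""
    if pnec is None or not pnec > 0:
        raise ValueError(f"invalid PNEC {pnec!r}: must be > 0")
    if mec < 0:
        raise ValueError(f"MEC must be >= 0, got {mec}")
    return mec / pnec


def classify_rq(rq: float) -> RiskBand:
    """Map an RQ value to its risk band (boundary at 0.1 resolves to NEGLIGIBLE)."""
    if rq < 0:
        raise ValueError(f"RQ must be >= 0, got {rq}")
    if rq <= 0.1:
        return RiskBand.NEGLIGIBLE
    if rq < 1:
        return RiskBand.LOW
    if rq < 10:
        return RiskBand.MODERATE
    return RiskBand.HIGH


def rq_table(
    table: ConcentrationTable,
    analytes: Sequence[AnalyteDef] | None = None,
    per_plant: bool = False,
) -> pd.DataFrame:
    """RQ report per analyte (MEC = across-plant mean concentration by default).

    With ``per_plant`` the MEC is each plant's mean and one row is emitted
    per (plant, analyte). Analytes lacking a PNEC get ``evaluable=False``.
    """
    defs = list(analytes) if analytes is not None else list(table.analytes.values())
    means = table.plant_means()
    rows = []

    def one(plant_label: str, mec: float, a: AnalyteDef) -> dict:
        if a.pnec is None:
            return {"wwtp_id": plant_label, "analyte_code": a.code, "mec_ng_L": mec,
                    "pnec_ng_L": float("nan"), "rq": float("nan"), "band": "",
                    "evaluable": False}
        rq = risk_quotient(mec, a.pnec)
        return {"wwtp_id": plant_label, "analyte_code": a.code, "mec_ng_L": mec,
                "pnec_ng_L": a.pnec, "rq": rq, "band": classify_rq(rq).value,
                "evaluable": True}

    for a in defs:
        if per_plant:
            for plant in means.index:
                rows.append(one(plant, float(means.loc[plant, a.code]), a))
        else:
            rows.append(one("ALL", float(means[a.code].mean()), a))
    return pd.DataFrame(rows)
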
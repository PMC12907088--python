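"""Literature removal-rate aggregation into per-plant, per-analyte fractions.

A literature entry is either a point removal rate or a range (whose midpoint
is used). The removal rate of compound j at plant i is the unweighted mean of
all literature entry values matching the plant's process class; if the plant
applies UV disinfection, UV entries for the compound join the averaging set
(optionally composed serially instead). Metabolites, lacking experimentally
verified removal data, inherit their parent compound's removal rate. The
plant-level rate is the unweighted mean over the parent panel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import AnalyteClass, AnalyteDef, WWTPRecord

__all__ = [
    "EntryKind",
    "LiteratureRR",
    "RRMatrix",
    "MissingRemovalDataError",
    "entry_value",
    "compound_rr",
    "build_rr_matrix",
    "rr_bounds_matrix",
    "read_literature",
    "write_literature",
]

LITERATURE_COLUMNS = ["process_class", "analyte_code", "kind", "value", "low", "high", "source_label"]


class EntryKind(str, enum.Enum):
    POINT = "POINT"
    RANGE = "RANGE"


class MissingRemovalDataError(ValueError):
    """Raised when one or more (process class, analyte) cells have no literature."""

    def __init__(self, gaps: Sequence[tuple[str, str]]):
        self.gaps = list(gaps)
        cells = ", ".join(f"({p}, {a})" for p, a in self.gaps)
        super().__init__(f"no literature removal data for cells: {cells}")


@dataclass(frozen=True)
class LiteratureRR:
    """One literature removal-rate entry (fractions in [0, 1])."""

    process_class: str
    analyte_code: str
    kind: EntryKind
    value: float | None = None
    low: float | None = None
    high: float | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.kind is EntryKind.POINT:
            if self.value is None or not 0 <= self.value <= 1:
                raise ValueError(f"POINT entry needs value in [0, 1], got {self.value}")
        else:
            if self.low is None or self.high is None:
                raise ValueError("RANGE entry needs low and high")
            if not (0 <= self.low <= self.high <= 1):
                raise ValueError(f"RANGE entry needs 0 <= low <= high <= 1, got [{self.low}, {self.high}]")


def entry_value(entry: LiteratureRR) -> float:
    """Point value of an entry: the value itself, or the range midpoint."""
    if entry.kind is EntryKind.POINT:
        return float(entry.value)
    return (float(entry.low) + float(entry.high)) / 2.0


def _entry_bounds(entry: LiteratureRR) -> tuple[float, float]:
    if entry.kind is EntryKind.POINT:
        return float(entry.value), float(entry.value)
    return float(entry.low), float(entry.high)


def compound_rr(
    entries: Sequence[LiteratureRR],
    uv_entries: Sequence[LiteratureRR] | None = None,
    has_uv: bool = False,
    uv_mode: str = "append_average",
) -> float:
    """Aggregate literature entries for one (process class, analyte) cell.

    Unweighted mean of entry values; with ``has_uv`` the UV entries either
    join the averaging set (``append_average``, default) or the UV mean is
    composed serially with the main-train mean: 1 - (1-a)(1-b).
    """
    if uv_mode not in ("append_average", "serial"):
        raise ValueError(f"uv_mode must be 'append_average' or 'serial', got {uv_mode!r}")
    if not entries:
        raise MissingRemovalDataError([("?", "?")])
    values = [entry_value(e) for e in entries]
    if has_uv and uv_entries:
        uv_values = [entry_value(e) for e in uv_entries]
        if uv_mode == "append_average":
            values = values + uv_values
        else:
            a = float(np.mean(values))
            b = float(np.mean(uv_values))
            return float(np.clip(1.0 - (1.0 - a) * (1.0 - b), 0.0, 1.0))
    return float(np.clip(np.mean(values), 0.0, 1.0))


@dataclass
class RRMatrix:
    """Removal fractions per (plant, analyte) plus per-plant means.

    ``rr`` is a plant x analyte DataFrame of fractions in [0, 1]; metabolite
    columns are copies of their parent's column; ``plant_mean`` is the
    unweighted mean over parent analytes.
    """

    rr: pd.DataFrame
    plant_mean: pd.Series

    def to_csv(self, path: str | Path) -> None:
        out = self.rr.copy()
        out["plant_mean"] = self.plant_mean
        out.to_csv(path, index_label="wwtp_id", float_format="%.17g")


def _group_entries(literature: Iterable[LiteratureRR]) -> dict[tuple[str, str], list[LiteratureRR]]:
    grouped: dict[tuple[str, str], list[LiteratureRR]] = {}
    for e in literature:
        grouped.setdefault((e.process_class, e.analyte_code), []).append(e)
    return grouped


def build_rr_matrix(
    registry: Sequence[WWTPRecord],
    literature: Iterable[LiteratureRR],
    analytes: Sequence[AnalyteDef],
    uv_mode: str = "append_average",
    uv_process: str = "UV",
    fallback_grand_mean: bool = False,
) -> RRMatrix:
    """Build the per-plant, per-analyte removal matrix from literature entries.

    Missing (process, parent-analyte) cells are a hard error listing every
    gap, unless ``fallback_grand_mean`` substitutes the process-class grand
    mean over available analytes.
    """
    grouped = _group_entries(literature)
    parents = [a for a in analytes if a.analyte_class is AnalyteClass.PARENT]
    metabolites = [a for a in analytes if a.analyte_class is AnalyteClass.METABOLITE]

    needed = sorted({(r.process_class.value, a.code) for r in registry for a in parents})
    gaps = [cell for cell in needed if cell not in grouped]
    if gaps and not fallback_grand_mean:
        raise MissingRemovalDataError(gaps)

    grand_mean: dict[str, float] = {}
    if fallback_grand_mean:
        for process in {p for p, _ in needed}:
            vals = [entry_value(e) for (p, _), es in grouped.items() if p == process for e in es]
            if vals:
                grand_mean[process] = float(np.clip(np.mean(vals), 0.0, 1.0))
        unfixable = [cell for cell in gaps if cell[0] not in grand_mean]
        if unfixable:
            raise MissingRemovalDataError(unfixable)

    rows = {}
    for rec in registry:
        row = {}
        for a in parents:
            cell = (rec.process_class.value, a.code)
            if cell in grouped:
                row[a.code] = compound_rr(
                    grouped[cell],
                    uv_entries=grouped.get((uv_process, a.code)),
                    has_uv=rec.has_uv,
                    uv_mode=uv_mode,
                )
            else:
                row[a.code] = grand_mean[rec.process_class.value]
        for m in metabolites:
            row[m.code] = row[m.parent_code]
        rows[rec.wwtp_id] = row
    rr = pd.DataFrame.from_dict(rows, orient="index")
    rr = rr.reindex(columns=[a.code for a in analytes])
    plant_mean = rr[[a.code for a in parents]].mean(axis=1)
    return RRMatrix(rr=rr, plant_mean=plant_mean)


def rr_bounds_matrix(
    registry: Sequence[WWTPRecord],
    literature: Iterable[LiteratureRR],
    analytes: Sequence[AnalyteDef],
    uv_process: str = "UV",
) -> tuple[pd.Series, pd.Series]:
    """Per-plant removal-rate bounds for uncertainty sampling.

    For each (plant, parent analyte): the min and max over the plant's
    applicable literature entry values (ranges contribute their endpoints,
    UV entries included when applied); plant-level bounds are the mean over
    parent analytes of the per-analyte bounds. Returns (low, high) Series
    indexed by wwtp_id, clipped to [0, 1].
    """
    grouped = _group_entries(literature)
    parents = [a for a in analytes if a.analyte_class is AnalyteClass.PARENT]
    lows, highs = {}, {}
    for rec in registry:
        lo_vals, hi_vals = [], []
        for a in parents:
            entries = list(grouped.get((rec.process_class.value, a.code), []))
            if rec.has_uv:
                entries += grouped.get((uv_process, a.code), [])
            if not entries:
                raise MissingRemovalDataError([(rec.process_class.value, a.code)])
            bounds = [_entry_bounds(e) for e in entries]
            lo_vals.append(min(b[0] for b in bounds))
            hi_vals.append(max(b[1] for b in bounds))
        lows[rec.wwtp_id] = float(np.clip(np.mean(lo_vals), 0.0, 1.0))
        highs[rec.wwtp_id] = float(np.clip(np.mean(hi_vals), 0.0, 1.0))
    return pd.Series(lows, name="rr_low"), pd.Series(highs, name="rr_high")


def read_literature(path: str | Path) -> list[LiteratureRR]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in LITERATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    entries = []
    for i, row in df.iterrows():
        kind = EntryKind(row["kind"].strip())
        entries.append(
            LiteratureRR(
                process_class=row["process_class"].strip(),
                analyte_code=row["analyte_code"].strip(),
                kind=kind,
                value=float(row["value"]) if row["value"].strip() else None,
                low=float(row["low"]) if row["low"].strip() else None,
                high=float(row["high"]) if row["high"].strip() else None,
                source_label=row["source_label"].strip(),
            )
        )
    return entries


def write_literature(entries: Sequence[LiteratureRR], path: str | Path) -> None:
    pd.DataFrame(
        {
            "process_class": [e.process_class for e in entries],
            "analyte_code": [e.analyte_code for e in entries],
            "kind": [e.kind.value for e in entries],
            "value": ["" if e.value is None else e.value for e in entries],
            "low": ["" if e.low is None else e.low for e in entries],
            "high": ["" if e.high is None else e.high for e in entries],
            "source_label": [e.source_label for e in entries],
        }
    ).to_csv(path, index=False, float_format="%.17g")
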
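"""Domain types, CSV schemas, and the non-detect censoring rule.

Concentrations are stored in ng/L throughout the package; unit conversion
happens only at the emission boundary. Values below the quantification
threshold are substituted with zero — a conservative, low-bound convention
for both concentrations and the emissions derived from them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProcessClass",
    "SourceGroup",
    "AnalyteClass",
    "WWTPRecord",
    "AnalyteDef",
    "ConcentrationRecord",
    "ConcentrationTable",
    "SchemaError",
    "censor_value",
    "read_registry",
    "write_registry",
    "read_analytes",
    "write_analytes",
    "read_concentrations",
    "write_concentrations",
    "REGISTRY_COLUMNS",
    "CONCENTRATION_COLUMNS",
    "ANALYTE_COLUMNS",
]


class SchemaError(ValueError):
    """Raised when a CSV row violates the declared schema; names row and column."""


class ProcessClass(str, enum.Enum):
    """Treatment-train class; AAO_LIKE covers AAO, SBR and Bardenpho trains."""

    AAO_LIKE = "AAO_LIKE"
    OXIDATION_DITCH = "OXIDATION_DITCH"


class SourceGroup(str, enum.Enum):
    """Land-use classification of the plant's service area."""

    G0_NONE = "G0_NONE"
    G1_INDUSTRIAL = "G1_INDUSTRIAL"
    G2_AGRICULTURAL = "G2_AGRICULTURAL"
    G3_BOTH = "G3_BOTH"


class AnalyteClass(str, enum.Enum):
    PARENT = "PARENT"
    METABOLITE = "METABOLITE"


@dataclass(frozen=True)
class WWTPRecord:
    """One plant's metadata.

    designed_capacity is in thousand t/a, discharge_volume in units of
    10^7 L/a (the volume unit of the emission mass balance).
    """

    wwtp_id: str
    district: str
    process_class: ProcessClass
    has_uv: bool
    designed_capacity: float
    served_population: float
    service_area: float
    source_group: SourceGroup
    discharge_volume: float

    def __post_init__(self) -> None:
        if not self.wwtp_id:
            raise ValueError("wwtp_id must be non-empty")
        for name in ("designed_capacity", "served_population", "service_area", "discharge_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 for plant {self.wwtp_id!r}")


@dataclass(frozen=True)
class AnalyteDef:
    """Analyte identity plus analytical thresholds and (optionally) a PNEC.

    parent_code is required for metabolites and forbidden for parents; the
    parent->metabolite map is many-to-one.
    """

    code: str
    analyte_class: AnalyteClass
    parent_code: str | None
    lod: float
    loq: float
    pnec: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.lod <= self.loq:
            raise ValueError(f"analyte {self.code!r}: need 0 < lod <= loq, got lod={self.lod}, loq={self.loq}")
        if self.analyte_class is AnalyteClass.METABOLITE and not self.parent_code:
            raise ValueError(f"metabolite {self.code!r} must declare a parent_code")
        if self.analyte_class is AnalyteClass.PARENT and self.parent_code:
            raise ValueError(f"parent {self.code!r} must not declare a parent_code")
        if self.pnec is not None and not self.pnec > 0:
            raise ValueError(f"analyte {self.code!r}: pnec must be > 0 when given")


_NON_DETECT_SENTINELS = {"<lod", "<loq", "nd", "n.d."}


def censor_value(raw: float | str, analyte: AnalyteDef, threshold: str = "loq") -> float:
    """Apply the non-detect substitution rule to one raw measurement.

    Values below the analyte's quantification threshold (LOQ by default,
    LOD via ``threshold="lod"``) are set to zero. Sentinel strings such as
    "<LOD" map to zero; a negative numeric value without a non-detect flag
    is invalid.
    """
    if threshold not in ("lod", "loq"):
        raise ValueError(f"threshold must be 'lod' or 'loq', got {threshold!r}")
    if isinstance(raw, str):
        if raw.strip().lower() in _NON_DETECT_SENTINELS:
            return 0.0
        try:
            raw = float(raw)
        except ValueError as exc:
            raise ValueError(f"malformed concentration value {raw!r}") from exc
    raw = float(raw)
    if np.isnan(raw):
        raise ValueError("concentration value is NaN")
    if raw < 0:
        raise ValueError(f"negative concentration {raw} without a non-detect flag")
    limit = analyte.loq if threshold == "loq" else analyte.lod
    return raw if raw >= limit else 0.0


@dataclass(frozen=True)
class ConcentrationRecord:
    """One censored-adjusted replicate measurement (ng/L)."""

    wwtp_id: str
    analyte_code: str
    replicate_id: str
    value: float

    def __post_init__(self) -> None:
        if not self.value >= 0:
            raise ValueError("censored-adjusted value must be >= 0")


class ConcentrationTable:
    """Replicate-level censored concentrations plus the analyte panel.

    Thin wrapper around a long-format DataFrame with helpers that implement
    the plant-mean convention used by every downstream statistic: the
    plant-level value of an analyte is the mean over its replicates, and a
    class total is the per-plant sum of member-analyte plant means.
    """

    def __init__(self, records: Iterable[ConcentrationRecord], analytes: Sequence[AnalyteDef]):
        self.analytes: dict[str, AnalyteDef] = {a.code: a for a in analytes}
        if len(self.analytes) != len(list(analytes)):
            raise ValueError("duplicate analyte codes in panel")
        for a in self.analytes.values():
            if a.parent_code is not None and a.parent_code not in self.analytes:
                raise ValueError(f"metabolite {a.code!r} references unknown parent {a.parent_code!r}")
        recs = list(records)
        for r in recs:
            if r.analyte_code not in self.analytes:
                raise ValueError(f"record references unknown analyte code {r.analyte_code!r}")
        self.frame = pd.DataFrame(
            {
                "wwtp_id": [r.wwtp_id for r in recs],
                "analyte_code": [r.analyte_code for r in recs],
                "replicate_id": [r.replicate_id for r in recs],
                "value_ng_L": [r.value for r in recs],
            }
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def plants(self) -> list[str]:
        return sorted(self.frame["wwtp_id"].unique())

    def codes(self, analyte_class: AnalyteClass | None = None) -> list[str]:
        codes = self.analytes.keys()
        if analyte_class is None:
            return list(codes)
        return [c for c in codes if self.analytes[c].analyte_class is analyte_class]

    def plant_means(self) -> pd.DataFrame:
        """Plant x analyte matrix of replicate means (missing cells -> 0)."""
        if self.frame.empty:
            return pd.DataFrame(columns=list(self.analytes))
        wide = (
            self.frame.groupby(["wwtp_id", "analyte_code"])["value_ng_L"]
            .mean()
            .unstack(fill_value=0.0)
        )
        return wide.reindex(columns=list(self.analytes), fill_value=0.0)

    def class_totals(self, analyte_class: AnalyteClass) -> pd.Series:
        """Per-plant sum of member-analyte plant means (ng/L)."""
        means = self.plant_means()
        cols = self.codes(analyte_class)
        return means[cols].sum(axis=1)

    def replicate_counts(self) -> pd.Series:
        return self.frame.groupby(["wwtp_id", "analyte_code"])["value_ng_L"].size()


REGISTRY_COLUMNS = [
    "wwtp_id",
    "district",
    "process_class",
    "has_uv",
    "designed_capacity_kt_a",
    "served_population",
    "service_area_km2",
    "source_group",
    "discharge_volume_1e7L_a",
]
CONCENTRATION_COLUMNS = ["wwtp_id", "analyte_code", "replicate_id", "value_ng_L"]
ANALYTE_COLUMNS = ["code", "analyte_class", "parent_code", "lod_ng_L", "loq_ng_L", "pnec_ng_L"]


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path: Path | str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_registry(path: str | Path) -> list[WWTPRecord]:
    """Read a plant registry CSV, validating every invariant row by row."""
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, REGISTRY_COLUMNS, path)
    records: list[WWTPRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        wid = row["wwtp_id"].strip()
        if wid in seen:
            raise SchemaError(f"{path}: row {rowno}, column wwtp_id: duplicate id {wid!r}")
        seen.add(wid)
        try:
            pc = ProcessClass(row["process_class"].strip())
        except ValueError:
            raise SchemaError(
                f"{path}: row {rowno}, column process_class: unknown value {row['process_class']!r}"
            ) from None
        try:
            sg = SourceGroup(row["source_group"].strip())
        except ValueError:
            raise SchemaError(
                f"{path}: row {rowno}, column source_group: unknown value {row['source_group']!r}"
            ) from None
        uv_raw = row["has_uv"].strip().lower()
        if uv_raw not in _BOOL_MAP:
            raise SchemaError(f"{path}: row {rowno}, column has_uv: not a boolean: {row['has_uv']!r}")
        numeric = {}
        for col, attr in [
            ("designed_capacity_kt_a", "designed_capacity"),
            ("served_population", "served_population"),
            ("service_area_km2", "service_area"),
            ("discharge_volume_1e7L_a", "discharge_volume"),
        ]:
            try:
                val = float(row[col])
            except ValueError:
                raise SchemaError(f"{path}: row {rowno}, column {col}: malformed number {row[col]!r}") from None
            if not val > 0:
                raise SchemaError(f"{path}: row {rowno}, column {col}: must be > 0, got {val}")
            numeric[attr] = val
        records.append(
            WWTPRecord(
                wwtp_id=wid,
                district=row["district"].strip(),
                process_class=pc,
                has_uv=_BOOL_MAP[uv_raw],
                source_group=sg,
                **numeric,
            )
        )
    return records


def write_registry(records: Sequence[WWTPRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "wwtp_id": [r.wwtp_id for r in records],
            "district": [r.district for r in records],
            "process_class": [r.process_class.value for r in records],
            "has_uv": [r.has_uv for r in records],
            "designed_capacity_kt_a": [r.designed_capacity for r in records],
            "served_population": [r.served_population for r in records],
            "service_area_km2": [r.service_area for r in records],
            "source_group": [r.source_group.value for r in records],
            "discharge_volume_1e7L_a": [r.discharge_volume for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_analytes(path: str | Path) -> list[AnalyteDef]:
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, ANALYTE_COLUMNS, path)
    defs: list[AnalyteDef] = []
    for i, row in df.iterrows():
        rowno = i + 2
        try:
            defs.append(
                AnalyteDef(
                    code=row["code"].strip(),
                    analyte_class=AnalyteClass(row["analyte_class"].strip()),
                    parent_code=row["parent_code"].strip() or None,
                    lod=float(row["lod_ng_L"]),
                    loq=float(row["loq_ng_L"]),
                    pnec=float(row["pnec_ng_L"]) if row["pnec_ng_L"].strip() else None,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {rowno}: {exc}") from None
    return defs


def write_analytes(defs: Sequence[AnalyteDef], path: str | Path) -> None:
    pd.DataFrame(
        {
            "code": [a.code for a in defs],
            "analyte_class": [a.analyte_class.value for a in defs],
            "parent_code": [a.parent_code or "" for a in defs],
            "lod_ng_L": [a.lod for a in defs],
            "loq_ng_L": [a.loq for a in defs],
            "pnec_ng_L": ["" if a.pnec is None else a.pnec for a in defs],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_concentrations(
    path: str | Path, analytes: Sequence[AnalyteDef], threshold: str = "loq"
) -> ConcentrationTable:
    """Read a long-format concentration CSV and apply the censoring rule."""
    panel = {a.code: a for a in analytes}
    df = pd.read_csv(path, dtype=str).fillna("")
    _check_columns(df, CONCENTRATION_COLUMNS, path)
    records: list[ConcentrationRecord] = []
    for i, row in df.iterrows():
        rowno = i + 2
        code = row["analyte_code"].strip()
        if code not in panel:
            raise SchemaError(f"{path}: row {rowno}, column analyte_code: unknown analyte {code!r}")
        try:
            value = censor_value(row["value_ng_L"], panel[code], threshold=threshold)
        except ValueError as exc:
            raise SchemaError(f"{path}: row {rowno}, column value_ng_L: {exc}") from None
        records.append(
            ConcentrationRecord(
                wwtp_id=row["wwtp_id"].strip(),
                analyte_code=code,
                replicate_id=row["replicate_id"].strip(),
                value=value,
            )
        )
    return ConcentrationTable(records, analytes)


def write_concentrations(table: ConcentrationTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.17g")
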
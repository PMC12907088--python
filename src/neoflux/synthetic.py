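"""Synthetic monitoring-data generator with known ground truth.

Emulates the study conditions of the suburban survey the pipeline is built
for: 21 plants across 5 districts, designed capacities log-uniform over the
printed range (912.5–73,000 thousand t/a), served populations proportional
to capacity, an 8-parent + 6-metabolite analyte panel, replicate-level
concentrations that depend linearly on served population (the generating
structure the extrapolation stage re-fits: y = alpha*population + beta + eps)
plus land-use group offsets, lognormal replicate noise, and LOD/LOQ
censoring. A truth sidecar records every generating parameter so downstream
stages can be tested for parameter recovery.

What it does not emulate: spatially explicit land use, rainfall/runoff
dynamics, in-sewer transformation kinetics, or correlated analyte panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import (
    AnalyteClass,
    AnalyteDef,
    ConcentrationRecord,
    ConcentrationTable,
    ProcessClass,
    SourceGroup,
    WWTPRecord,
    censor_value,
)
from .panel import default_panel
from .removal import EntryKind, LiteratureRR

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "generate_registry",
    "generate_concentrations",
    "generate_literature_rr",
    "write_truth_json",
    "CAPACITY_RANGE_KT_A",
    "UV_PROCESS",
]

# printed individual-capacity range, thousand t/a
CAPACITY_RANGE_KT_A = (912.5, 73_000.0)
# pseudo process class under which UV-disinfection removal entries are filed
UV_PROCESS = "UV"

_DISTRICTS = ("QP", "MH", "SJ", "FX", "JS")


@dataclass
class SyntheticTruth:
    """Generating parameters: the ground truth recovery tests check against.

    slope/intercept are per analyte (ng/L per person and ng/L); group_effects
    are additive class-level ng/L offsets per land-use source group (G0 is the
    zero reference), split evenly over the analytes of the class; true_rr maps
    (process_class, analyte_code) to a removal fraction in [0, 1].
    """

    slope: dict[str, float]
    intercept: dict[str, float]
    residual_sd: dict[str, float]
    group_effects: dict[str, dict[str, float]]
    true_rr: dict[tuple[str, str], float]
    replicate_cv: float = 0.2

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual_sd must be >= 0")
        if any(not 0 <= rr <= 1 for rr in self.true_rr.values()):
            raise ValueError("true_rr must lie in [0, 1]")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        for cls, eff in self.group_effects.items():
            if eff.get(SourceGroup.G0_NONE.value, 0.0) != 0.0:
                raise ValueError("group effect for G0_NONE must be 0 (reference group)")

    def class_slope(self, analytes: Sequence[AnalyteDef], analyte_class: AnalyteClass) -> float:
        return sum(self.slope[a.code] for a in analytes if a.analyte_class is analyte_class)

    def class_intercept(self, analytes: Sequence[AnalyteDef], analyte_class: AnalyteClass) -> float:
        return sum(self.intercept[a.code] for a in analytes if a.analyte_class is analyte_class)


# Relative analyte weights within each class, mimicking the skewed field
# composition (NIT and DIN dominate parents; DN-IMI and DIN-U dominate
# metabolites). Used to split class-level means over analytes.
_PARENT_WEIGHTS = {
    "NIT": 0.55, "DIN": 0.21, "IMI": 0.10, "THIA": 0.05,
    "ACE": 0.04, "IMID": 0.03, "THI": 0.012, "CLO": 0.008,
}
_METABOLITE_WEIGHTS = {
    "DN-IMI": 0.60, "DIN-U": 0.25, "IMI-urea": 0.06,
    "N-DM-ACE": 0.05, "N-DN-THIA": 0.03, "5-OH-IMI": 0.01,
}


def default_truth(
    analytes: Sequence[AnalyteDef] | None = None,
    residual_sd_frac: float = 0.25,
    replicate_cv: float = 0.2,
) -> SyntheticTruth:
    """Default generating parameters for the emulated survey.

    Class-level targets at the mean served population (~240k persons):
    parent totals around 570 ng/L and metabolite totals around 480 ng/L,
    roughly half carried by the population slope and half by the intercept.
    Per-analyte residual sd defaults to 25% of the analyte's intercept-scale
    level. Removal fractions sit in the 0.05–0.55 band so that plant means
    land in the 25–48% range conventional trains achieve.
    """
    analytes = list(analytes) if analytes is not None else default_panel()
    pop_ref = 240_000.0
    class_level = {AnalyteClass.PARENT: 570.0, AnalyteClass.METABOLITE: 480.0}
    weights = {AnalyteClass.PARENT: _PARENT_WEIGHTS, AnalyteClass.METABOLITE: _METABOLITE_WEIGHTS}
    slope: dict[str, float] = {}
    intercept: dict[str, float] = {}
    residual_sd: dict[str, float] = {}
    for a in analytes:
        w = weights[a.analyte_class][a.code]
        level = class_level[a.analyte_class] * w
        slope[a.code] = 0.5 * level / pop_ref
        intercept[a.code] = 0.5 * level
        residual_sd[a.code] = residual_sd_frac * level

    group_effects = {
        AnalyteClass.PARENT.value: {
            SourceGroup.G0_NONE.value: 0.0,
            SourceGroup.G1_INDUSTRIAL.value: 40.0,
            SourceGroup.G2_AGRICULTURAL.value: 250.0,
            SourceGroup.G3_BOTH.value: 350.0,
        },
        AnalyteClass.METABOLITE.value: {
            SourceGroup.G0_NONE.value: 0.0,
            SourceGroup.G1_INDUSTRIAL.value: 180.0,
            SourceGroup.G2_AGRICULTURAL.value: 80.0,
            SourceGroup.G3_BOTH.value: 260.0,
        },
    }

    base_rr = {
        "ACE": 0.30, "CLO": 0.25, "DIN": 0.20, "IMI": 0.45,
        "IMID": 0.35, "NIT": 0.50, "THI": 0.40, "THIA": 0.28,
    }
    true_rr: dict[tuple[str, str], float] = {}
    for code, rr in base_rr.items():
        true_rr[(ProcessClass.AAO_LIKE.value, code)] = rr
        true_rr[(ProcessClass.OXIDATION_DITCH.value, code)] = min(rr + 0.05, 1.0)
        true_rr[(UV_PROCESS, code)] = min(rr + 0.20, 1.0)
    return SyntheticTruth(
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        group_effects=group_effects,
        true_rr=true_rr,
        replicate_cv=replicate_cv,
    )


def noise_free_truth(analytes: Sequence[AnalyteDef] | None = None) -> SyntheticTruth:
    """Truth with every noise term and group offset zeroed (exact-linear limit)."""
    truth = default_truth(analytes, residual_sd_frac=0.0, replicate_cv=0.0)
    for cls in truth.group_effects:
        truth.group_effects[cls] = {g: 0.0 for g in truth.group_effects[cls]}
    return truth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_registry(
    n_plants: int,
    seed: int,
    districts: Sequence[str] = _DISTRICTS,
    uv_probability: float = 0.3,
) -> list[WWTPRecord]:
    """Generate a plant registry with capacities log-uniform in the printed range.

    Served population is proportional to designed capacity (about 8.3 persons
    per thousand t/a, the survey-wide ratio) with multiplicative lognormal
    noise; discharge volume is capacity converted to 10^7 L/a times a
    utilisation factor in [0.7, 0.95].
    """
    if n_plants < 2:
        raise ValueError("n_plants must be >= 2")
    rng = _rng(seed, 101)
    lo, hi = CAPACITY_RANGE_KT_A
    capacity = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_plants))
    population = capacity * 8.3 * np.exp(rng.normal(0.0, 0.15, size=n_plants))
    area = population / 3500.0 * np.exp(rng.normal(0.0, 0.2, size=n_plants))
    process_opts = [ProcessClass.AAO_LIKE, ProcessClass.OXIDATION_DITCH]
    process = rng.choice(len(process_opts), size=n_plants, p=[0.7, 0.3])
    has_uv = rng.random(n_plants) < uv_probability
    group_opts = list(SourceGroup)
    groups = rng.choice(len(group_opts), size=n_plants, p=[0.3, 0.2, 0.3, 0.2])
    # 1 thousand t = 10^6 L, so capacity in kt/a is capacity/10 in 10^7 L/a
    volume = capacity / 10.0 * rng.uniform(0.7, 0.95, size=n_plants)
    district_idx = rng.integers(0, len(districts), size=n_plants)

    counters: dict[str, int] = {}
    records = []
    for i in range(n_plants):
        d = districts[district_idx[i]]
        counters[d] = counters.get(d, 0) + 1
        records.append(
            WWTPRecord(
                wwtp_id=f"{d}W-{counters[d]}",
                district=d,
                process_class=process_opts[process[i]],
                has_uv=bool(has_uv[i]),
                designed_capacity=float(capacity[i]),
                served_population=float(population[i]),
                service_area=float(area[i]),
                source_group=group_opts[groups[i]],
                discharge_volume=float(volume[i]),
            )
        )
    return records


def expected_plant_mean(record: WWTPRecord, truth: SyntheticTruth, analyte: AnalyteDef,
                        n_class_analytes: int) -> float:
    """Noise-free expected concentration for one (plant, analyte) cell."""
    eff = truth.group_effects[analyte.analyte_class.value][record.source_group.value]
    mu = (
        truth.slope[analyte.code] * record.served_population
        + truth.intercept[analyte.code]
        + eff / n_class_analytes
    )
    return max(mu, 0.0)


def generate_concentrations(
    registry: Sequence[WWTPRecord],
    truth: SyntheticTruth,
    n_replicates: int,
    seed: int,
    analytes: Sequence[AnalyteDef] | None = None,
    censor_threshold: str = "loq",
) -> ConcentrationTable:
    """Draw replicate-level censored concentrations for every (plant, analyte).

    Per cell: mean = slope*population + intercept + group offset + eps with
    eps ~ Normal(0, residual_sd); replicates lognormal around the mean with
    coefficient of variation replicate_cv; negative/below-threshold values
    censored to zero via the core rule.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    analytes = list(analytes) if analytes is not None else default_panel()
    n_by_class = {
        cls: sum(1 for a in analytes if a.analyte_class is cls) for cls in AnalyteClass
    }
    rng = _rng(seed, 202)
    cv = truth.replicate_cv
    sigma_ln = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    records: list[ConcentrationRecord] = []
    for rec in registry:
        for a in analytes:
            mu = expected_plant_mean(rec, truth, a, n_by_class[a.analyte_class])
            mu = mu + rng.normal(0.0, truth.residual_sd[a.code]) if truth.residual_sd[a.code] > 0 else mu
            mu = max(mu, 0.0)
            for k in range(n_replicates):
                if mu == 0.0:
                    raw = 0.0
                elif sigma_ln > 0:
                    raw = mu * np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                else:
                    raw = mu
                records.append(
                    ConcentrationRecord(
                        wwtp_id=rec.wwtp_id,
                        analyte_code=a.code,
                        replicate_id=f"r{k + 1}",
                        value=censor_value(max(raw, 0.0), a, threshold=censor_threshold),
                    )
                )
    return ConcentrationTable(records, analytes)


def generate_literature_rr(
    truth: SyntheticTruth,
    n_entries_per_cell: int = 4,
    spread: float = 0.1,
    seed: int = 0,
) -> list[LiteratureRR]:
    """Emit point and range literature entries centred on the true removal rates.

    Each entry's central value is true_rr + Uniform(-spread, spread); range
    entries get a half-width drawn in [0, spread/2] so their midpoint equals
    the centre. All values are clipped to [0, 1]. With spread = 0 every entry
    equals true_rr exactly and aggregation recovers it.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    if n_entries_per_cell < 1:
        raise ValueError("n_entries_per_cell must be >= 1")
    rng = _rng(seed, 303)
    entries: list[LiteratureRR] = []
    for (process, code), rr in sorted(truth.true_rr.items()):
        for k in range(n_entries_per_cell):
            center = float(np.clip(rr + rng.uniform(-spread, spread), 0.0, 1.0))
            if k % 2 == 0:
                entries.append(
                    LiteratureRR(
                        process_class=process, analyte_code=code, kind=EntryKind.POINT,
                        value=center, source_label=f"syn-{process}-{code}-{k}",
                    )
                )
            else:
                w = float(rng.uniform(0.0, spread / 2)) if spread > 0 else 0.0
                w = min(w, center, 1.0 - center)  # keep midpoint = center after clipping
                entries.append(
                    LiteratureRR(
                        process_class=process, analyte_code=code, kind=EntryKind.RANGE,
                        low=center - w, high=center + w,
                        source_label=f"syn-{process}-{code}-{k}",
                    )
                )
    return entries


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    """Persist generating parameters as a JSON sidecar for recovery tests."""
    payload = {
        "slope": truth.slope,
        "intercept": truth.intercept,
        "residual_sd": truth.residual_sd,
        "group_effects": truth.group_effects,
        "true_rr": {f"{p}|{c}": v for (p, c), v in truth.true_rr.items()},
        "replicate_cv": truth.replicate_cv,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth_json(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        slope=payload["slope"],
        intercept=payload["intercept"],
        residual_sd=payload["residual_sd"],
        group_effects=payload["group_effects"],
        true_rr={tuple(k.split("|")): v for k, v in payload["true_rr"].items()},
        replicate_cv=payload["replicate_cv"],
    )
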
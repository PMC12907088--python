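"""End-to-end pipeline orchestration: data -> occurrence -> ratios -> removal
-> regression -> emission -> Monte Carlo -> risk, with every stage persisted
as tidy CSV under the run directory and logged with stage, seed and row
counts. Stages can be re-run individually from their persisted inputs.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core_data, emission, extrapolation, monte_carlo, occurrence, pm_ratio, removal, risk, synthetic
from .core_data import AnalyteClass
from .panel import default_panel

__all__ = ["StageError", "run_pipeline", "load_config", "STAGES", "default_config"]

STAGES = ["data", "occurrence", "ratios", "rr", "fit", "emit", "mc", "risk"]

log = logging.getLogger("neoflux")


class StageError(RuntimeError):
    """Wraps a stage failure, naming the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def default_config() -> dict:
    """Default simulate-mode configuration mirroring the emulated survey."""
    return {
        "mode": "simulate",
        "seed": 1,
        "out_dir": "results/run",
        "simulate": {
            "n_plants": 21,
            "n_city_plants": 60,
            "n_replicates": 5,
            "literature_entries_per_cell": 4,
            "literature_spread": 0.10,
        },
        "inputs": {},
        "options": {
            "censor_threshold": "loq",
            "covariate": "population",
            "uv_mode": "append_average",
            "target_r2": 0.95,
            "alpha_sig": 0.05,
            "mc_iterations": 100_000,
            "flow_cv": 0.10,
            "analytical_cv": 0.125,
        },
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _covariate_value(record: core_data.WWTPRecord, covariate: str) -> float:
    if covariate == "population":
        return record.served_population
    if covariate == "capacity":
        return record.designed_capacity
    raise ValueError(f"unknown covariate {covariate!r}")


# ---------------------------------------------------------------- stage: data

def _stage_data(cfg: dict, out: Path, ctx: dict) -> None:
    opts = cfg["options"]
    if cfg["mode"] == "simulate":
        sim = cfg["simulate"]
        seed = int(cfg["seed"])
        analytes = default_panel()
        truth = synthetic.default_truth(analytes)
        n_sampled = int(sim["n_plants"])
        n_city = int(sim.get("n_city_plants", n_sampled))
        if n_city < n_sampled:
            raise ValueError("n_city_plants must be >= n_plants")
        city = synthetic.generate_registry(n_city, seed=seed)
        sampled = city[:n_sampled]
        table = synthetic.generate_concentrations(
            sampled, truth, n_replicates=int(sim["n_replicates"]), seed=seed,
            analytes=analytes, censor_threshold=opts["censor_threshold"],
        )
        literature = synthetic.generate_literature_rr(
            truth,
            n_entries_per_cell=int(sim["literature_entries_per_cell"]),
            spread=float(sim["literature_spread"]),
            seed=seed,
        )
        synthetic.write_truth_json(truth, out / "truth.json")
        ctx["truth"] = truth
    else:
        paths = cfg["inputs"]
        for key in ("registry", "concentrations", "literature", "analytes"):
            if key not in paths:
                raise FileNotFoundError(f"config inputs missing {key!r}")
        analytes = core_data.read_analytes(paths["analytes"])
        sampled = core_data.read_registry(paths["registry"])
        city = (
            core_data.read_registry(paths["city_registry"])
            if paths.get("city_registry")
            else sampled
        )
        table = core_data.read_concentrations(
            paths["concentrations"], analytes, threshold=opts["censor_threshold"]
        )
        literature = removal.read_literature(paths["literature"])
    core_data.write_analytes(analytes, out / "analytes.csv")
    core_data.write_registry(sampled, out / "registry.csv")
    core_data.write_registry(city, out / "city_registry.csv")
    core_data.write_concentrations(table, out / "concentrations.csv")
    removal.write_literature(literature, out / "literature.csv")
    ctx.update(analytes=analytes, registry=sampled, city_registry=city,
               table=table, literature=literature)
    log.info("stage=data seed=%s plants=%d city_plants=%d records=%d",
             cfg["seed"], len(sampled), len(city), len(table))


def _load_data(out: Path, cfg: dict, ctx: dict) -> None:
    analytes = core_data.read_analytes(out / "analytes.csv")
    ctx.update(
        analytes=analytes,
        registry=core_data.read_registry(out / "registry.csv"),
        city_registry=core_data.read_registry(out / "city_registry.csv"),
        table=core_data.read_concentrations(
            out / "concentrations.csv", analytes, threshold=cfg["options"]["censor_threshold"]
        ),
        literature=removal.read_literature(out / "literature.csv"),
    )


# ----------------------------------------------------------- analysis stages

def _stage_occurrence(cfg: dict, out: Path, ctx: dict) -> None:
    table, registry = ctx["table"], ctx["registry"]
    occurrence.detection_frequency_table(table).to_csv(out / "detection_frequency.csv", index=False)
    occurrence.summarize(table, "analyte").to_csv(out / "summary_analyte.csv", index=False)
    occurrence.summarize(table, "analyte-class").to_csv(out / "summary_class.csv", index=False)
    occurrence.composition_profile(table, registry).to_csv(out / "composition.csv", index=False)
    comp = []
    for cls in AnalyteClass:
        gc = occurrence.group_compare(table, registry, cls)
        gc.pairwise["analyte_class"] = cls.value
        comp.append(gc.pairwise)
    pd.concat(comp, ignore_index=True).to_csv(out / "group_tests.csv", index=False)
    occurrence.correlate_with_registry(table, registry).to_csv(out / "correlations.csv", index=False)
    log.info("stage=occurrence analytes=%d plants=%d", len(table.analytes), len(table.plants))


def _stage_ratios(cfg: dict, out: Path, ctx: dict) -> None:
    results = pm_ratio.pm_ratios(ctx["table"])
    pm_ratio.ratios_to_frame(results).to_csv(out / "ratios.csv", index=False)
    pm_ratio.ratio_summary(results).to_csv(out / "ratio_summary.csv", index=False)
    means, tests = pm_ratio.pm_ratio_by_group(results, ctx["registry"])
    means.to_csv(out / "ratio_group_means.csv", index=False)
    tests.to_csv(out / "ratio_group_tests.csv", index=False)
    ctx["ratios"] = results
    log.info("stage=ratios n=%d excluded=%d", len(results), sum(r.excluded for r in results))


def _stage_rr(cfg: dict, out: Path, ctx: dict) -> None:
    rr = removal.build_rr_matrix(
        ctx["city_registry"], ctx["literature"], ctx["analytes"],
        uv_mode=cfg["options"]["uv_mode"],
    )
    rr.to_csv(out / "rr_matrix.csv")
    ctx["rr"] = rr
    log.info("stage=rr plants=%d range=%.3f-%.3f", len(rr.plant_mean),
             rr.plant_mean.min(), rr.plant_mean.max())


def _load_rr(out: Path, cfg: dict, ctx: dict) -> None:
    df = pd.read_csv(out / "rr_matrix.csv", index_col="wwtp_id", float_precision="round_trip")
    ctx["rr"] = removal.RRMatrix(rr=df.drop(columns=["plant_mean"]), plant_mean=df["plant_mean"])


def _stage_fit(cfg: dict, out: Path, ctx: dict) -> None:
    opts = cfg["options"]
    covariate = opts["covariate"]
    table, registry = ctx["table"], ctx["registry"]
    by_id = {r.wwtp_id: r for r in registry}
    fits: dict[str, extrapolation.RegressionFit] = {}
    for cls in AnalyteClass:
        totals = table.class_totals(cls)
        points = [
            (pid, _covariate_value(by_id[pid], covariate), float(totals[pid]))
            for pid in totals.index if pid in by_id
        ]
        fits[cls.value] = extrapolation.fit_with_pruning(
            points, target_r2=float(opts["target_r2"]), covariate=covariate
        )
    extrapolation.fit_to_frame(fits).to_csv(out / "fits.csv", index=False, float_format="%.17g")

    sampled_ids = {r.wwtp_id for r in registry}
    rows = []
    for rec in ctx["city_registry"]:
        if rec.wwtp_id in sampled_ids:
            continue
        for cls in AnalyteClass:
            pred = extrapolation.predict_interval(
                fits[cls.value], _covariate_value(rec, covariate),
                alpha_sig=float(opts["alpha_sig"]), plant=rec.wwtp_id,
            )
            rows.append(
                {"wwtp_id": rec.wwtp_id, "analyte_class": cls.value,
                 "mean": pred.mean, "sd_pred": pred.sd_pred,
                 "lower": pred.lower, "upper": pred.upper}
            )
    pd.DataFrame(rows, columns=["wwtp_id", "analyte_class", "mean", "sd_pred", "lower", "upper"]
                 ).to_csv(out / "predictions.csv", index=False, float_format="%.17g")
    ctx["fits"] = fits
    ctx["predictions"] = pd.DataFrame(rows)
    log.info("stage=fit covariate=%s r2=%s", covariate,
             {k: round(f.r_squared, 3) for k, f in fits.items()})


def _load_fit(out: Path, cfg: dict, ctx: dict) -> None:
    fits = {}
    for row in pd.read_csv(out / "fits.csv", float_precision="round_trip").itertuples():
        excluded = [] if pd.isna(row.excluded_ids) or not row.excluded_ids else str(row.excluded_ids).split(";")
        fits[row.response] = extrapolation.RegressionFit(
            covariate=row.covariate, slope=row.slope, intercept=row.intercept,
            residual_sd=row.residual_sd, n_retained=int(row.n_retained),
            r_squared=row.r_squared, x_mean=row.x_mean, s_xx=row.s_xx,
            retained_ids=[], excluded_ids=excluded, below_target=bool(row.below_target),
        )
    ctx["fits"] = fits
    ctx["predictions"] = pd.read_csv(out / "predictions.csv", float_precision="round_trip")


def _class_conc_stats(ctx: dict) -> dict[tuple[str, str], tuple[float, float]]:
    """(plant, class) -> (mean, standard error) of measured class totals."""
    table: core_data.ConcentrationTable = ctx["table"]
    stats: dict[tuple[str, str], tuple[float, float]] = {}
    df = table.frame
    for cls in AnalyteClass:
        codes = table.codes(cls)
        sub = df[df["analyte_code"].isin(codes)]
        rep_totals = sub.groupby(["wwtp_id", "replicate_id"])["value_ng_L"].sum()
        for plant, vals in rep_totals.groupby(level=0):
            n = len(vals)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            stats[(plant, cls.value)] = (float(vals.mean()), se)
    return stats


def _emission_inputs(cfg: dict, ctx: dict) -> list[monte_carlo.PlantClassInput]:
    """Assemble per-(plant, class) concentration/RR/volume inputs city-wide.

    Sampled plants carry their measured mean and standard error; unsampled
    plants carry the regression prediction and its sd. Removal bounds come
    from the plant's literature entry-value min/max.
    """
    rr: removal.RRMatrix = ctx["rr"]
    measured = _class_conc_stats(ctx)
    preds = ctx["predictions"]
    pred_map = {
        (row.wwtp_id, row.analyte_class): (max(float(row.mean), 0.0), float(row.sd_pred))
        for row in preds.itertuples()
    } if len(preds) else {}
    rr_low, rr_high = removal.rr_bounds_matrix(
        ctx["city_registry"], ctx["literature"], ctx["analytes"]
    )
    inputs = []
    missing = []
    for rec in ctx["city_registry"]:
        for cls in AnalyteClass:
            key = (rec.wwtp_id, cls.value)
            if key in measured:
                conc_mean, conc_sd = measured[key]
            elif key in pred_map:
                conc_mean, conc_sd = pred_map[key]
            else:
                missing.append(key)
                continue
            inputs.append(
                monte_carlo.PlantClassInput(
                    wwtp_id=rec.wwtp_id, analyte_class=cls.value,
                    conc_mean=conc_mean, conc_sd=conc_sd,
                    rr_mean=float(rr.plant_mean[rec.wwtp_id]),
                    rr_low=float(rr_low[rec.wwtp_id]), rr_high=float(rr_high[rec.wwtp_id]),
                    volume=rec.discharge_volume, region=rec.district,
                )
            )
    if missing:
        raise ValueError(f"plants without measured or predicted concentrations: {sorted(missing)}")
    return inputs


def _stage_emit(cfg: dict, out: Path, ctx: dict) -> None:
    inputs = _emission_inputs(cfg, ctx)
    estimates = [
        emission.EmissionEstimate(
            wwtp_id=i.wwtp_id, analyte_class=i.analyte_class, region=i.region,
            influent_load=emission.annual_load(i.conc_mean, i.volume),
            effluent_emission=emission.point_emission(i.conc_mean, i.rr_mean, i.volume),
        )
        for i in inputs
    ]
    emission.estimates_to_frame(estimates).to_csv(out / "emissions.csv", index=False)
    totals, shares = emission.aggregate(estimates, by="class")
    totals.to_csv(out / "emission_totals.csv", index=False)
    shares.to_csv(out / "emission_shares.csv", index=False)
    region_totals, _ = emission.aggregate(estimates, by="region")
    region_totals.to_csv(out / "emission_by_region.csv", index=False)
    ctx["estimates"] = estimates
    ctx["mc_inputs"] = inputs
    log.info("stage=emit cells=%d total_emission=%s", len(estimates),
             {r.group: round(r.effluent_emission, 2) for r in totals.itertuples()})


def _stage_mc(cfg: dict, out: Path, ctx: dict) -> None:
    opts = cfg["options"]
    inputs = ctx.get("mc_inputs") or _emission_inputs(cfg, ctx)
    config = monte_carlo.UncertaintyConfig(
        n_iterations=int(opts["mc_iterations"]), seed=int(cfg["seed"]),
        flow_cv=float(opts["flow_cv"]), analytical_cv=float(opts["analytical_cv"]),
    )
    result = monte_carlo.run_mc(inputs, config)
    result.per_plant.to_csv(out / "mc_per_plant.csv", index=False)
    result.per_region.to_csv(out / "mc_regional.csv", index=False)
    attributions = []
    for cls in AnalyteClass:
        att = monte_carlo.variance_attribution(inputs, config, analyte_class=cls.value)
        att["analyte_class"] = cls.value
        attributions.append(att)
    pd.concat(attributions, ignore_index=True).to_csv(out / "mc_attribution.csv", index=False)
    ctx["mc"] = result
    city = result.per_region[result.per_region["region"] == "ALL"]
    log.info("stage=mc iterations=%d seed=%s citywide=%s", config.n_iterations, cfg["seed"],
             {r.analyte_class: f"{r.mean:.2f}+/-{r.sd:.2f}" for r in city.itertuples()})


def _stage_risk(cfg: dict, out: Path, ctx: dict) -> None:
    report = risk.rq_table(ctx["table"], ctx["analytes"])
    report.to_csv(out / "risk.csv", index=False)
    ctx["risk"] = report
    log.info("stage=risk evaluable=%d/%d", int(report["evaluable"].sum()), len(report))


def _write_summary(out: Path, ctx: dict) -> None:
    lines = ["run summary", "==========="]
    if "estimates" in ctx:
        totals, _ = emission.aggregate(ctx["estimates"], by="class")
        for row in totals.itertuples():
            lines.append(
                f"{row.group}: load {row.influent_load:.2f} kg/a, emission "
                f"{row.effluent_emission:.2f} kg/a, removed {row.removed_mass:.2f} kg/a "
                f"({row.removal_pct:.2f}%)"
            )
    if "mc" in ctx:
        city = ctx["mc"].per_region
        for row in city[city["region"] == "ALL"].itertuples():
            lines.append(
                f"{row.analyte_class} city-wide MC: {row.mean:.2f} +/- {row.sd:.2f} kg/a "
                f"[{row.ci_lower:.2f}, {row.ci_upper:.2f}]"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "data": _stage_data,
    "occurrence": _stage_occurrence,
    "ratios": _stage_ratios,
    "rr": _stage_rr,
    "fit": _stage_fit,
    "emit": _stage_emit,
    "mc": _stage_mc,
    "risk": _stage_risk,
}
_STAGE_LOADERS = {"data": _load_data, "rr": _load_rr, "fit": _load_fit}


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    stages: Sequence[str] | None = None,
) -> dict[str, Any]:
    """Execute the pipeline (or a subset of stages) and persist all outputs.

    ``config`` is a dict or a YAML path; ``seed``/``out_dir`` override the
    config. When a stage subset is given, earlier stages' persisted outputs
    in ``out_dir`` are loaded as inputs. Returns the stage context (tables,
    fits, estimates, MC result).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else {**default_config(), **{
        k: ({**default_config()[k], **v} if isinstance(v, Mapping) and isinstance(default_config().get(k), dict) else v)
        for k, v in config.items()
    }}
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)

    requested = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    ctx: dict[str, Any] = {}
    for stage in STAGES:
        if stage not in requested:
            loader = _STAGE_LOADERS.get(stage)
            if loader is not None and (out / ("analytes.csv" if stage == "data" else "fits.csv" if stage == "fit" else "rr_matrix.csv")).exists():
                loader(out, cfg, ctx)
            continue
        try:
            _STAGE_FUNCS[stage](cfg, out, ctx)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
    _write_summary(out, ctx)
    return ctx
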
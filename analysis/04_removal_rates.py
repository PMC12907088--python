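"""Aggregate the literature removal-rate table into the per-plant,
per-analyte removal matrix (metabolites inherit parent rates; UV entries
join the averaging set where applied)."""

import pandas as pd

from neoflux.pipeline import run_pipeline

ctx = run_pipeline({"out_dir": "results/survey"}, stages=["rr"])

rr = ctx["rr"]
print(f"removal matrix: {rr.rr.shape[0]} plants x {rr.rr.shape[1]} analytes")
print(f"plant-mean removal rates: {100 * rr.plant_mean.min():.1f}% - "
      f"{100 * rr.plant_mean.max():.1f}%")
by_analyte = rr.rr.mean()
print("highest/lowest compound removal:",
      by_analyte.idxmax(), f"{100 * by_analyte.max():.1f}%,",
      by_analyte.idxmin(), f"{100 * by_analyte.min():.1f}%")
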
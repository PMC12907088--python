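"""Occurrence statistics on the sampled plants: detection frequencies,
class-total concentration summaries, district composition profiles, land-use
group contrasts (Welch t), and covariate correlations."""

import pandas as pd

from neoflux.pipeline import run_pipeline

ctx = run_pipeline({"out_dir": "results/survey"}, stages=["occurrence"])

summary = pd.read_csv("results/survey/summary_class.csv").set_index("scope")
for cls in ("PARENT", "METABOLITE"):
    row = summary.loc[cls]
    print(f"{cls.lower()} class totals: mean {row['mean']:.1f} ng/L "
          f"(range {row['min']:.1f}-{row['max']:.1f})")

det = pd.read_csv("results/survey/detection_frequency.csv")
print(f"analytes at 100% detection: {(det['percent'] == 100).sum()}/{len(det)}")

corr = pd.read_csv("results/survey/correlations.csv")
pop = corr[(corr["covariate"] == "served_population")].set_index("analyte_class")
print(f"parent totals vs population: r = {pop.loc['PARENT', 'r']:.3f} "
      f"(p = {pop.loc['PARENT', 'p']:.3f})")

tests = pd.read_csv("results/survey/group_tests.csv")
sig = tests[(~tests["skipped"].astype(bool)) & (tests["p"] < 0.05)]
print(f"significant land-use group contrasts (p<0.05): {len(sig)}")
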
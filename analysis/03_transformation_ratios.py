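"""Parent/metabolite transformation ratios per plant and pair, with the
>100 outlier exclusion, plus land-use group contrasts of the total ratio."""

import pandas as pd

from neoflux.pipeline import run_pipeline

run_pipeline({"out_dir": "results/survey"}, stages=["ratios"])

summary = pd.read_csv("results/survey/ratio_summary.csv").set_index("pair")
for pair, row in summary.iterrows():
    print(f"{pair}: {row['mean']:.2f} +/- {row['sd']:.2f} "
          f"(n={row['n_included']:.0f}, excluded {row['n_excluded']:.0f})")

groups = pd.read_csv("results/survey/ratio_group_means.csv")
print("total-ratio group means:",
      {r.group: round(r.mean, 2) for r in groups.itertuples()})
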
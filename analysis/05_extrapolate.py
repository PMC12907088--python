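"""Fit class-total influent concentration against served population on the
sampled plants (with influence-based pruning toward R^2 >= 0.95) and predict
concentrations with prediction intervals for the unsampled plants."""

import pandas as pd

from neoflux.pipeline import run_pipeline

ctx = run_pipeline({"out_dir": "results/survey"}, stages=["fit"])

for label, fit in ctx["fits"].items():
    flag = " (below target)" if fit.below_target else ""
    print(f"{label}: slope {fit.slope:.3e} ng/L per person, intercept "
          f"{fit.intercept:.1f} ng/L, sigma {fit.residual_sd:.1f} ng/L, "
          f"R^2 {fit.r_squared:.3f}, n={fit.n_retained}, "
          f"excluded {fit.excluded_ids}{flag}")

preds = pd.read_csv("results/survey/predictions.csv")
print(f"predicted {preds['wwtp_id'].nunique()} unsampled plants; "
      f"parent-class prediction sd {preds[preds.analyte_class == 'PARENT']['sd_pred'].mean():.1f} ng/L on average")
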
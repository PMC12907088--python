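"""Risk-quotient screening of mean influent concentrations against PNECs,
with the four-band classification; metabolites without PNECs are reported
as not evaluable."""

import pandas as pd

from neoflux.pipeline import run_pipeline

run_pipeline({"out_dir": "results/survey"}, stages=["risk"])

report = pd.read_csv("results/survey/risk.csv")
evaluable = report[report["evaluable"]]
print("band counts:", evaluable["band"].value_counts().to_dict())
worst = evaluable.nlargest(3, "rq")
for row in worst.itertuples():
    print(f"{row.analyte_code}: RQ {row.rq:.2f} ({row.band})")
print(f"not evaluable (no PNEC): {(~report['evaluable']).sum()} analytes")
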
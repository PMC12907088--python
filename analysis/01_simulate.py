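"""Generate the synthetic monitoring campaign: a 60-plant regional registry
(21 plants sampled with 5 replicates each across 14 analytes), a literature
removal-rate table, and the ground-truth sidecar. All downstream scripts
read from results/survey/."""

import sys
from pathlib import Path

from neoflux.pipeline import run_pipeline

OUT = Path("results/survey")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

ctx = run_pipeline({"out_dir": str(OUT)}, seed=SEED, stages=["data"])

table = ctx["table"]
print(f"simulated {len(ctx['registry'])} sampled plants of {len(ctx['city_registry'])} "
      f"in the region (seed {SEED})")
print(f"concentration records: {len(table)} over {len(table.analytes)} analytes")
caps = [r.designed_capacity for r in ctx["city_registry"]]
print(f"designed capacities: {min(caps):.1f} - {max(caps):.1f} thousand t/a")
print(f"outputs in {OUT}/ (registry, concentrations, literature, truth.json)")
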
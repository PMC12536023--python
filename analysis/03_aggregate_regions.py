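"""Aggregate parcel-level PAF into the 10 lobar macro-regions.

Valid parcel estimates are averaged within each macro-region (cingulate,
frontal, occipital, parietal, temporal x hemisphere); macro-regions with
no valid parcel are missing.  Writes the long-format PAF table and the
per-group validity proportions under results/cohort/.
"""

import sys

import pandas as pd

from pafreact import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = PipelineConfig(seed=seed, out_dir="results/cohort", stages=("aggregate",))
out = run_pipeline(cfg)

table = pd.read_csv(out / "paf_table.csv")
validity = pd.read_csv(out / "validity.csv")
print(f"PAF table: {len(table)} rows, {table.paf_hz.isna().mean():.1%} missing")
print("\nparcel-level validity (% of estimates in 7-13 Hz), by group:")
rng = validity.groupby("diagnosis").valid_pct.agg(["min", "max", "mean"]).round(1)
print(rng)
print("\nsubjects contributing per macro-region (min-max across regions):")
per = table.dropna(subset=["paf_hz"]).groupby(
    ["diagnosis", "condition", "region"]
).subject.nunique().groupby(["diagnosis", "condition"]).agg(["min", "max"])
print(per)
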
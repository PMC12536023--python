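"""Simulate the study cohort: 29 TD and 22 ASD children, ages 60-95
months, with per-parcel spectral parameters for two recording conditions
(dark-room rest vs eyes-open video viewing).

Writes covariates, generative truth and parcel-level spectral parameters
under results/cohort/.
"""

import sys

from pafreact import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = PipelineConfig(seed=seed, out_dir="results/cohort", stages=("simulate",))
out = run_pipeline(cfg)

import pandas as pd

covs = pd.read_csv(out / "covariates.csv")
print(f"cohort written to {out}")
print(covs.groupby("diagnosis").agg(
    n=("subject", "count"),
    mean_age_months=("age_months", "mean"),
    pct_male=("sex", "mean"),
    mean_srs=("srs_total", "mean"),
).round(2))
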
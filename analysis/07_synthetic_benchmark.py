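"""Validate the analysis stages on synthetic surveys with known truth.

Finding: at the generator's default separation (within-group log-scale
correlation 0.9, independent groups) variable-mode Ward clustering
recovers the planted three-group partition exactly (ARI = 1), and the
censoring machinery reproduces its configured non-detect rates.
"""

from pathlib import Path

import pandas as pd

from coastrisk.sample_io import write_survey
from coastrisk.synthetic_data import (
    GeneratorConfig, generate_survey, planted_partition_check,
    table1_like_config,
)

SEED = 5

out = Path(__file__).resolve().parent.parent / "results"
out.mkdir(exist_ok=True)

survey, truth = generate_survey(GeneratorConfig(n_samples=200, seed=SEED))
ari = planted_partition_check(survey, truth)

emulated, emu_truth = generate_survey(table1_like_config(seed=SEED))
write_survey(emulated, out / "07_synthetic_survey.csv")
nd = sum(m.nondetect for r in emulated.records
         for m in r.measurements.values())

pd.Series({"planted_partition_ari": ari,
           "emulated_nd_cells": nd,
           "emulated_hotspots": len(emu_truth.hotspot_rows)}
          ).to_csv(out / "07_synthetic_benchmark.csv")
print(f"planted-partition ARI: {ari}")
print(f"emulated survey: {nd} ND cells, hotspot rows {emu_truth.hotspot_rows}")
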
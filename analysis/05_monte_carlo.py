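"""Probabilistic risk: 10,000-iteration Monte Carlo over the default
distribution template (lognormal concentrations moment-matched to the
survey, truncated-normal body weight, uniform ingestion rate).

Finding: the 5th-95th percentile CR bands for Cd, Cr and Pb sit above
the 1e-4 acceptability threshold for both receptors, and the child band
sits above the adult band throughout, echoing the deterministic chain.
"""

from pathlib import Path

from coastrisk import mc_risk
from coastrisk.sample_io import load_reference_registry, load_table1_metals

SEED = 1
N = 10_000

out = Path(__file__).resolve().parent.parent / "results"
out.mkdir(exist_ok=True)

registry = load_reference_registry()
survey = load_table1_metals()
conc, exposure = mc_risk.default_mc_specs(survey, registry)
results = mc_risk.mc_survey_risk(conc, registry, n=N, seed=SEED,
                                 exposure_specs=exposure)
frame = mc_risk.results_frame(results)
frame.to_csv(out / "05_mc_report.csv")

cr_cols = ["cr_p5", "cr_mean", "cr_p95", "cr_exceedance"]
print(frame.loc[(["Cd", "Cr", "Pb"], slice(None), "oral"), cr_cols]
      .round(6).to_string())
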
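#!/usr/bin/env python
"""Internal validation of the fitted model on the held-out 40%.

Calibration: expected-to-observed ratio per 2-year horizon (expected = mean
predicted risk from baseline profiles; observed = Kaplan-Meier cumulative
incidence), with SMR-style confidence intervals, overall and in risk-factor
subgroups at the 10-year horizon. Discrimination: AUC per horizon among
women observable at that horizon, with Hanley-McNeil intervals.
"""

import dataclasses
import warnings
from pathlib import Path

import pandas as pd

from screenrisk import load_cohort, validate_model
from screenrisk.cohort import CohortTable
from screenrisk.pc_cox import ModelFit

root = Path(__file__).resolve().parents[1]
scratch = root / "scratch"
results = root / "results"

cohort = load_cohort(scratch / "cohort" / "visits.csv", scratch / "cohort" / "outcomes.csv")
est_ids = set(pd.read_csv(scratch / "estimation_women.csv").woman_id)
val = CohortTable(
    cohort.visits[~cohort.visits.woman_id.isin(est_ids)].reset_index(drop=True),
    cohort.outcomes[~cohort.outcomes.woman_id.isin(est_ids)].reset_index(drop=True),
)
fit = ModelFit.from_json(scratch / "fit.json")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    report = validate_model(fit, val, subgroup_tau=10.0)

table3 = report["per_horizon"]
table3.to_csv(results / "table3.csv", index=False)
print("calibration and discrimination per horizon:")
print(table3.round(3).to_string(index=False))

table4 = pd.DataFrame([dataclasses.asdict(c) for c in report["subgroups"]])
table4.to_csv(results / "table4.csv", index=False)
print("\n10-year subgroup calibration:")
print(table4[["subgroup", "O", "eo_ratio", "ci_low", "ci_high"]].round(3).to_string(index=False))
print(f"\nwrote {results / 'table3.csv'} and {results / 'table4.csv'}")
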
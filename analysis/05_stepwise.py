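#!/usr/bin/env python
"""Stepwise regression starting from the three derived measures.

Forward-backward p-value stepwise (enter/remove at 0.05): start with the
three visit frequencies alone, gradually admit demographic candidates,
and watch which derived measures survive -- a redundancy probe for the
information the mobility measures share with socioeconomic covariates.

    python analysis/05_stepwise.py --seed 1 --out results/study
"""

import argparse
import json
from pathlib import Path

from neighvisit import filter_tracts, standardize, stepwise_regression
from neighvisit.config import MEASURE_COLUMNS
from neighvisit.io import read_measures, read_tables, write_json

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/study"))
args = parser.parse_args()

tracts, _, _ = read_tables(
    args.out / "tracts.csv", args.out / "pois.csv", args.out / "visits.csv"
)
measures = read_measures(args.out / "measures.csv")
filtered, _ = filter_tracts(tracts)
baseline_vars = json.loads((args.out / "vif_trace.json").read_text())["retained"]

frame = filtered.merge(measures, on="tract_id", how="left")
design, _, _ = standardize(frame[baseline_vars + list(MEASURE_COLUMNS)])
trace = stepwise_regression(
    design, frame["obesity_prevalence"].to_numpy(float),
    start_vars=list(MEASURE_COLUMNS), candidate_vars=baseline_vars,
)
write_json(trace.to_dict(), args.out / "stepwise_trace.json")

print(f"three measures alone: R2 = {trace.start_r2:.3f}")
for step in trace.steps:
    extra = f" (triggered by {step['triggered_by']})" if "triggered_by" in step else ""
    print(f"  {step['action']:4s} {step['variable']:28s} "
          f"p={step['p_value']:.4f}  R2={step['r2']:.3f}{extra}")
survivors = [m for m in MEASURE_COLUMNS if m in trace.final_variables]
print(f"final model: {len(trace.final_variables)} variables; "
      f"derived measures retained: {survivors or 'none'}")
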
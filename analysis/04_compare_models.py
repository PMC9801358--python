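#!/usr/bin/env python
"""Baseline-vs-test comparison across the five models.

Fits OLS, GWR, RF, DNN and GRF on the post-cascade demographic set
(baseline) and on that set plus the three derived visit frequencies
(test).  Statistical models report in-sample R2 / adjusted R2 / AIC /
RMSE; machine-learning models report pooled tenfold-CV R2 / RMSE.  Also
aggregates RF importances across the ten training folds.

    python analysis/04_compare_models.py --seed 1 --out results/study
"""

import argparse
import json
from pathlib import Path

from neighvisit import (
    ModelSpec,
    filter_tracts,
    run_baseline_and_test,
    standardize,
)
from neighvisit.comparison import cross_validate_importances, aggregate_importance
from neighvisit.config import MEASURE_COLUMNS
from neighvisit.io import read_measures, read_tables, write_json

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/study"))
parser.add_argument("--folds", type=int, default=10)
args = parser.parse_args()

tracts, _, _ = read_tables(
    args.out / "tracts.csv", args.out / "pois.csv", args.out / "visits.csv"
)
measures = read_measures(args.out / "measures.csv")
filtered, _ = filter_tracts(tracts)
baseline_vars = json.loads((args.out / "vif_trace.json").read_text())["retained"]

specs = [ModelSpec(kind=k, seed=args.seed) for k in ("ols", "gwr", "rf", "dnn", "grf")]
report = run_baseline_and_test(filtered, measures, baseline_vars, specs,
                               seed=args.seed, k_folds=args.folds)
write_json(report.to_dict(), args.out / "comparison_report.json")
(args.out / "comparison_report.md").write_text(report.to_markdown() + "\n")
print(report.to_markdown())

frame = filtered.merge(measures, on="tract_id", how="left")
design, _, _ = standardize(frame[baseline_vars + list(MEASURE_COLUMNS)])
folds = cross_validate_importances(
    ModelSpec(kind="rf", seed=args.seed), design,
    frame["obesity_prevalence"].to_numpy(float), k=args.folds, seed=args.seed,
)
imp = aggregate_importance(folds)
imp.to_csv(args.out / "rf_importance.csv", index=False)
print("\ntop RF mean importances across folds:")
print(imp.head(8).to_string(index=False))
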
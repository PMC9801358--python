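#!/usr/bin/env python
"""Tract filtering, spatial autocorrelation, and multicollinearity.

Applies the exclusion rule (fewer than 50 residents or missing outcome),
computes global Moran's I of obesity prevalence under row-standardized
8-nearest-neighbor weights with a 999-draw permutation test, runs the
VIF elimination cascade (cut-off 5) on the 24 demographic covariates,
and correlates each derived measure with the outcome.

    python analysis/03_diagnostics.py --seed 1 --out results/study
"""

import argparse
from pathlib import Path

import pandas as pd

from neighvisit import (
    build_weights,
    correlations,
    filter_tracts,
    morans_i,
    standardize,
    vif_cascade,
)
from neighvisit.config import DEMOGRAPHIC_COLUMNS, MEASURE_COLUMNS
from neighvisit.io import read_measures, read_tables, write_json

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/study"))
parser.add_argument("--knn", type=int, default=8)
parser.add_argument("--permutations", type=int, default=999)
args = parser.parse_args()

tracts, _, _ = read_tables(
    args.out / "tracts.csv", args.out / "pois.csv", args.out / "visits.csv"
)
measures = read_measures(args.out / "measures.csv")
filtered, excl = filter_tracts(tracts)
print(f"{excl['n_excluded']} of {excl['n_total']} tracts "
      f"({excl['pct_excluded']:.1f}%) excluded "
      "(under 50 residents or missing prevalence)")

weights = build_weights(filtered, k=args.knn)
moran = morans_i(filtered["obesity_prevalence"].to_numpy(float), weights,
                 n_permutations=args.permutations, seed=args.seed)
moran["exclusion"] = excl
write_json(moran, args.out / "moran.json")
print(f"global Moran's I of obesity prevalence: {moran['I']:.3f} "
      f"(E[I]={moran['expected_I']:.4f}, permutation p={moran['p_value']:.4f})")

demo = [c for c in DEMOGRAPHIC_COLUMNS if c in filtered.columns]
z, _, _ = standardize(filtered[demo])
trace = vif_cascade(z)
write_json(trace.to_dict(), args.out / "vif_trace.json")
print(f"VIF cascade: {len(trace.rounds)} rounds, removed "
      f"{trace.removed_variables()}, {len(trace.retained)} variables retained "
      f"(max final VIF {max(trace.final_vifs.values()):.2f})")

frame = filtered.merge(measures, on="tract_id", how="left")
rows = []
for m in MEASURE_COLUMNS:
    c = correlations(frame[m].to_numpy(float),
                     frame["obesity_prevalence"].to_numpy(float))
    rows.append({"measure": m, **c})
    print(f"  {m:16s} Pearson r={c['pearson_r']:+.3f}  "
          f"Spearman rho={c['spearman_rho']:+.3f}")
pd.DataFrame(rows).to_csv(args.out / "correlations.csv", index=False)
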
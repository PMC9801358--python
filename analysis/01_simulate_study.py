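#!/usr/bin/env python
"""Generate the synthetic study: tracts, POIs, censored visit panel, outcome.

Emulates the structure of the real inputs (an aggregated mobility panel
with privacy censoring, census covariates with compositional
collinearity, a spatially autocorrelated obesity outcome) at the default
study size of 900 tracts, and reports how hard the privacy censoring
bites.

    python analysis/01_simulate_study.py --seed 1 --out results/study
"""

import argparse
from pathlib import Path

from neighvisit import SimulationConfig, simulate_study
from neighvisit.io import (
    write_centroids_geojson,
    write_json,
    write_pois,
    write_tracts,
    write_visits,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/study"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(seed=args.seed)
study = simulate_study(config)
write_tracts(study["tracts"], args.out / "tracts.csv")
write_pois(study["pois"], args.out / "pois.csv")
write_visits(study["visits"], args.out / "visits.csv")
write_centroids_geojson(study["tracts"], args.out / "centroids.geojson")
write_json(study["ground_truth"], args.out / "ground_truth.json")

true, kept = study["true_visits"], study["visits"]
dropped = len(true) - len(kept)
censored = int((kept["recorded_count"] == 4).sum())
print(f"{config.n_tracts} tracts, {len(study['pois'])} POIs")
print(f"{len(true)} true (tract, POI) visit pairs")
print(f"privacy censoring removed {dropped} single-visitor records "
      f"({100 * dropped / len(true):.1f}%)")
print(f"{censored} of {len(kept)} surviving records ({100 * censored / len(kept):.1f}%) "
      f"are recorded as the censored value 4")
print(f"artifacts written to {args.out}")
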
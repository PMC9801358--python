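"""End-to-end pipeline: simulate -> derive -> diagnose -> compare -> stepwise.

Each stage writes its artifacts into one output directory and is skipped
on rerun when its outputs already exist for the same config hash (pass
``force=True`` to recompute).  Every JSON artifact embeds the config hash
and master seed; the log records seeds, exclusion counts, and every
elimination round, so a run is auditable after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nv_io
from .comparison import (
    aggregate_importance,
    cross_validate_importances,
    filter_tracts,
    run_baseline_and_test,
    stepwise_regression,
)
from .config import DEMOGRAPHIC_COLUMNS, MEASURE_COLUMNS, SimulationConfig
from .measures import DEFAULT_ALPHA, derive_measures
from .models import ModelSpec
from .simulate import simulate_study
from .spatial import VIF_CUTOFF, build_weights, correlations, morans_i, standardize, vif_cascade

log = logging.getLogger("neighvisit")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = DEFAULT_ALPHA
    impute: bool = True
    knn: int = 8
    cutoff: float = VIF_CUTOFF
    permutations: int = 999
    k_folds: int = 10
    p_enter: float = 0.05
    p_remove: float = 0.05
    seed: int = 0
    model_kinds: tuple[str, ...] = ("ols", "gwr", "rf", "dnn", "grf")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["model_kinds"] = list(self.model_kinds)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.simulation = SimulationConfig.from_dict(sim) if sim else SimulationConfig()
        if "model_kinds" in d:
            cfg.model_kinds = tuple(d["model_kinds"])
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(cfg: PipelineConfig, obj: dict) -> dict:
    obj = dict(obj)
    obj["config_hash"] = cfg.hash()
    obj["seed"] = cfg.seed
    return obj


def default_model_specs(cfg: PipelineConfig) -> list[ModelSpec]:
    specs = []
    for kind in cfg.model_kinds:
        specs.append(ModelSpec(kind=kind, seed=cfg.seed))
    return specs


def run_pipeline(cfg: PipelineConfig, out_dir: Path, force: bool = False) -> dict:
    """Execute every stage, reusing on-disk intermediates when possible.

    Returns a dict with the main in-memory artifacts.  Artifacts written:
    tracts.csv, pois.csv, visits.csv, measures.csv, ground_truth.json,
    diagnostics (vif_trace.json, moran.json, correlations.csv),
    comparison_report.json (+ .md), rf_importance.csv, and
    stepwise_trace.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.simulation.seed = cfg.seed if cfg.simulation.seed == 0 else cfg.simulation.seed
    chash = cfg.hash()

    def fresh(*names: str) -> bool:
        if force:
            return False
        for name in names:
            p = out / name
            if not p.exists():
                return False
            if name.endswith(".json"):
                try:
                    if json.loads(p.read_text()).get("config_hash") not in (None, chash):
                        return False
                except (json.JSONDecodeError, AttributeError):
                    return False
        return True

    # ---- stage 1: simulate -------------------------------------------
    if fresh("tracts.csv", "pois.csv", "visits.csv", "ground_truth.json"):
        log.info("simulate: reusing intermediates in %s", out)
        tracts, pois, visits = nv_io.read_tables(
            out / "tracts.csv", out / "pois.csv", out / "visits.csv"
        )
    else:
        log.info("simulate: n_tracts=%d seed=%d", cfg.simulation.n_tracts, cfg.seed)
        study = simulate_study(cfg.simulation)
        tracts, pois, visits = study["tracts"], study["pois"], study["visits"]
        nv_io.write_tracts(tracts, out / "tracts.csv")
        nv_io.write_pois(pois, out / "pois.csv")
        nv_io.write_visits(visits, out / "visits.csv")
        nv_io.write_centroids_geojson(tracts, out / "centroids.geojson")
        nv_io.write_json(_stamp(cfg, study["ground_truth"]), out / "ground_truth.json")
        tracts = nv_io._public(tracts)

    # ---- stage 2: derive measures ------------------------------------
    if fresh("measures.csv"):
        log.info("derive: reusing measures.csv")
        measures = nv_io.read_measures(out / "measures.csv")
    else:
        measures = derive_measures(
            visits, pois, tracts, impute=cfg.impute, alpha=cfg.alpha, seed=cfg.seed
        )
        nv_io.write_measures(measures, out / "measures.csv")
        log.info("derive: alpha=%.2f impute=%s", cfg.alpha, cfg.impute)

    # ---- stage 3: filter + diagnose ----------------------------------
    filtered, exclusion = filter_tracts(tracts)
    log.info(
        "filter: excluded %d of %d tracts (%.1f%%)",
        exclusion["n_excluded"], exclusion["n_total"], exclusion["pct_excluded"],
    )
    demo_cols = [c for c in DEMOGRAPHIC_COLUMNS if c in filtered.columns]
    design_z, _, _ = standardize(filtered[demo_cols])

    if fresh("vif_trace.json", "moran.json"):
        trace_d = json.loads((out / "vif_trace.json").read_text())
        baseline_vars = trace_d["retained"]
        log.info("diagnose: reusing vif_trace.json / moran.json")
    else:
        trace = vif_cascade(design_z, cutoff=cfg.cutoff)
        baseline_vars = trace.retained
        for i, rnd in enumerate(trace.rounds, 1):
            log.info("vif cascade round %d: removed %s", i, rnd["removed"])
        nv_io.write_json(_stamp(cfg, trace.to_dict()), out / "vif_trace.json")
        weights = build_weights(filtered, k=cfg.knn)
        moran = morans_i(
            filtered["obesity_prevalence"].to_numpy(float),
            weights,
            n_permutations=cfg.permutations,
            seed=cfg.seed,
        )
        moran["exclusion"] = exclusion
        nv_io.write_json(_stamp(cfg, moran), out / "moran.json")
        log.info("moran: I=%.3f p=%.4f", moran["I"], moran["p_value"])

    frame = filtered.merge(measures, on="tract_id", how="left")
    corr_rows = []
    for m in MEASURE_COLUMNS:
        c = correlations(
            frame[m].to_numpy(float), frame["obesity_prevalence"].to_numpy(float)
        )
        corr_rows.append({"measure": m, **c})
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

    # ---- stage 4: baseline vs test comparison ------------------------
    if fresh("comparison_report.json"):
        log.info("compare: reusing comparison_report.json")
        report_dict = json.loads((out / "comparison_report.json").read_text())
        report = None
    else:
        specs = default_model_specs(cfg)
        report = run_baseline_and_test(
            filtered, measures, baseline_vars, specs, seed=cfg.seed, k_folds=cfg.k_folds
        )
        report_dict = _stamp(cfg, report.to_dict())
        nv_io.write_json(report_dict, out / "comparison_report.json")
        (out / "comparison_report.md").write_text(report.to_markdown() + "\n")

        rf_spec = ModelSpec(kind="rf", seed=cfg.seed)
        test_design, _, _ = standardize(frame[baseline_vars + list(MEASURE_COLUMNS)])
        fold_imps = cross_validate_importances(
            rf_spec, test_design, frame["obesity_prevalence"].to_numpy(float),
            k=cfg.k_folds, seed=cfg.seed,
        )
        aggregate_importance(fold_imps).to_csv(out / "rf_importance.csv", index=False)

    # ---- stage 5: stepwise -------------------------------------------
    if fresh("stepwise_trace.json"):
        log.info("stepwise: reusing stepwise_trace.json")
        stepwise = json.loads((out / "stepwise_trace.json").read_text())
    else:
        full_design, _, _ = standardize(frame[baseline_vars + list(MEASURE_COLUMNS)])
        trace = stepwise_regression(
            full_design,
            frame["obesity_prevalence"].to_numpy(float),
            start_vars=list(MEASURE_COLUMNS),
            candidate_vars=baseline_vars,
            p_enter=cfg.p_enter,
            p_remove=cfg.p_remove,
        )
        stepwise = _stamp(cfg, trace.to_dict())
        nv_io.write_json(stepwise, out / "stepwise_trace.json")
        log.info(
            "stepwise: start R2=%.3f, final set size %d",
            stepwise["start_r2"], len(stepwise["final_variables"]),
        )

    return {
        "tracts": tracts,
        "pois": pois,
        "visits": visits,
        "measures": measures,
        "filtered": filtered,
        "exclusion": exclusion,
        "baseline_variables": baseline_vars,
        "report": report_dict,
        "stepwise": stepwise,
        "out_dir": out,
    }
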
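"""The baseline-vs-test experiment, cross-validation, and stepwise search.

The experiment asks whether the three mobility-derived visit-frequency
measures improve tract-level obesity estimation beyond socioeconomic and
demographic covariates.  Two analysis sets are fitted per model:

* **baseline** -- the post-elimination demographic variables only;
* **test** -- baseline plus the three visit frequencies.

Reporting convention: the statistical models (OLS, GWR) report in-sample
R2 / adjusted R2 / AIC / RMSE; the machine-learning models (RF, DNN, GRF)
report R2 / RMSE from pooled tenfold cross-validation.  Improvements are
flagged at three decimal places, ties reported as ties, and a per-model
failure (e.g. the network refusing a 77-tract city) is recorded as an
annotated cell rather than aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

from .config import MEASURE_COLUMNS
from .errors import EmptyAnalysisError, InvalidConfigError, NeighvisitError, SchemaError
from .models import ModelResult, ModelSpec, fit_model
from .spatial import standardize

STATISTICAL_KINDS = ("ols", "gwr")
ML_KINDS = ("rf", "dnn", "grf")

MIN_POPULATION = 50  # tracts with fewer residents are excluded
TIE_DECIMALS = 3  # improvement flags compare metrics rounded to 3 decimals


def filter_tracts(
    tracts: pd.DataFrame, min_population: int = MIN_POPULATION
) -> tuple[pd.DataFrame, dict]:
    """Drop tracts with fewer than ``min_population`` residents or a
    missing obesity prevalence; a population of exactly the floor is
    retained.  Returns (filtered table, exclusion summary)."""
    for col in ("population", "obesity_prevalence"):
        if col not in tracts.columns:
            raise SchemaError(f"tract table missing column {col!r}")
    n = len(tracts)
    keep = (tracts["population"] >= min_population) & tracts[
        "obesity_prevalence"
    ].notna()
    out = tracts[keep].reset_index(drop=True)
    if len(out) == 0:
        raise EmptyAnalysisError("tract filtering removed every row")
    excluded = int(n - keep.sum())
    return out, {
        "n_total": n,
        "n_excluded": excluded,
        "n_retained": int(keep.sum()),
        "pct_excluded": 100.0 * excluded / n if n else 0.0,
    }


def cross_validate(
    spec: ModelSpec,
    design: pd.DataFrame,
    outcome: np.ndarray,
    coords: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Pooled k-fold out-of-fold R2 and RMSE with a seeded partition."""
    y = np.asarray(outcome, float)
    n = len(y)
    if k > n:
        raise InvalidConfigError(f"k ({k}) exceeds n ({n})")
    if spec.kind == "grf" and spec.eager_locals:
        # out-of-fold prediction only needs local forests at the test
        # points' nearest training tracts; train them on demand
        spec = replace(spec, eager_locals=False)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(n)
    for train, test in folds.split(design):
        tr_design = design.iloc[train]
        tr_coords = coords[train] if coords is not None else None
        te_coords = coords[test] if coords is not None else None
        result = fit_model(spec, tr_design, y[train], tr_coords)
        pooled[test] = result.predict(design.iloc[test], te_coords)
    resid = y - pooled
    return {
        "r2": 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum()),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }


def cross_validate_importances(
    spec: ModelSpec,
    design: pd.DataFrame,
    outcome: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Per-fold forest importances (one forest per training fold)."""
    y = np.asarray(outcome, float)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for train, _ in folds.split(design):
        res = fit_model(spec, design.iloc[train], y[train], None)
        out.append(dict(res.importances))
    return out


def aggregate_importance(fold_results: list[dict[str, float]]) -> pd.DataFrame:
    """Mean importance per variable across folds, sorted descending with
    ranks."""
    if not fold_results:
        raise InvalidConfigError("need at least one fold result")
    keys = set(fold_results[0])
    for fr in fold_results[1:]:
        if set(fr) != keys:
            raise SchemaError("fold results have inconsistent variable sets")
    frame = pd.DataFrame(fold_results)
    means = frame.mean().sort_values(ascending=False)
    return pd.DataFrame(
        {
            "variable": means.index,
            "mean_importance": means.to_numpy(),
            "rank": np.arange(1, len(means) + 1),
        }
    )


@dataclass
class ComparisonReport:
    """Per (model x analysis-set) metrics with improvement flags."""

    cells: dict = field(default_factory=dict)  # kind -> set_label -> metrics/error
    flags: dict = field(default_factory=dict)  # kind -> metric -> improved|tie|worse
    exclusion: dict = field(default_factory=dict)
    baseline_variables: list[str] = field(default_factory=list)
    test_variables: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cells": self.cells,
            "flags": self.flags,
            "exclusion": self.exclusion,
            "baseline_variables": self.baseline_variables,
            "test_variables": self.test_variables,
        }

    def to_markdown(self) -> str:
        lines = ["| model | metric | baseline | test | verdict |", "|---|---|---|---|---|"]
        for kind, sets in self.cells.items():
            base, test = sets.get("baseline", {}), sets.get("test", {})
            if "error" in base or "error" in test:
                msg = base.get("error") or test.get("error")
                lines.append(f"| {kind} | - | - | - | {msg} |")
                continue
            for metric in base:
                verdict = self.flags.get(kind, {}).get(metric, "")
                lines.append(
                    f"| {kind} | {metric} | {base[metric]:.3f} | "
                    f"{test[metric]:.3f} | {verdict} |"
                )
        return "\n".join(lines)


def _improvement(metric: str, base: float, test: float) -> str:
    b, t = round(base, TIE_DECIMALS), round(test, TIE_DECIMALS)
    if b == t:
        return "tie"
    higher_better = metric in ("r2", "adjusted_r2")
    improved = t > b if higher_better else t < b
    return "improved" if improved else "worse"


def run_baseline_and_test(
    tracts: pd.DataFrame,
    measures: pd.DataFrame,
    baseline_variables: list[str],
    specs: list[ModelSpec],
    seed: int = 0,
    k_folds: int = 10,
    standardize_measures: bool = True,
) -> ComparisonReport:
    """Fit every model on the baseline and test analysis sets.

    ``tracts`` must already be filtered; ``baseline_variables`` should be
    the post-elimination demographic set.  The three visit-frequency
    measures are appended (standardized with the rest by default) to form
    the test set.  Per-model failures become annotated cells.
    """
    frame = tracts.merge(measures, on="tract_id", how="left", validate="1:1")
    if frame[list(MEASURE_COLUMNS)].isna().any().any():
        raise SchemaError("measures missing for some filtered tracts")
    y = frame["obesity_prevalence"].to_numpy(float)
    coords = frame[["x", "y"]].to_numpy(float)

    base_design, _, _ = standardize(frame[baseline_variables])
    if standardize_measures:
        test_design, _, _ = standardize(
            frame[baseline_variables + list(MEASURE_COLUMNS)]
        )
    else:
        meas = frame[list(MEASURE_COLUMNS)]
        test_design = pd.concat([base_design, meas], axis=1)

    report = ComparisonReport(
        baseline_variables=list(baseline_variables),
        test_variables=list(baseline_variables) + list(MEASURE_COLUMNS),
    )
    for spec in specs:
        cells: dict[str, dict] = {}
        for label, design in (("baseline", base_design), ("test", test_design)):
            try:
                if spec.kind in STATISTICAL_KINDS:
                    res: ModelResult = fit_model(spec, design, y, coords)
                    metrics = {
                        m: res.metrics[m]
                        for m in ("r2", "rmse", "adjusted_r2", "aic")
                        if m in res.metrics
                    }
                    if spec.kind == "gwr":
                        metrics["bandwidth"] = res.bandwidth
                else:
                    metrics = cross_validate(spec, design, y, coords, k=k_folds, seed=seed)
            except NeighvisitError as exc:
                cells[label] = {"error": f"{type(exc).__name__}: {exc}"}
            else:
                cells[label] = metrics
        report.cells[spec.kind] = cells
        if "error" not in cells["baseline"] and "error" not in cells["test"]:
            report.flags[spec.kind] = {
                m: _improvement(m, cells["baseline"][m], cells["test"][m])
                for m in ("r2", "rmse", "adjusted_r2", "aic")
                if m in cells["baseline"] and m in cells["test"]
            }
    return report


# ---------------------------------------------------------------- stepwise


@dataclass
class StepwiseTrace:
    """Ordered add/drop steps of a p-value stepwise regression."""

    steps: list[dict] = field(default_factory=list)
    final_variables: list[str] = field(default_factory=list)
    start_r2: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "final_variables": self.final_variables,
            "start_r2": self.start_r2,
        }


def _ols_pvalues(design: pd.DataFrame, y: np.ndarray) -> tuple[pd.Series, float]:
    exog = sm.add_constant(design.to_numpy(float), has_constant="add")
    fit = sm.OLS(y, exog).fit()
    pvals = pd.Series(fit.pvalues[1:], index=design.columns)
    return pvals, float(fit.rsquared)


def stepwise_regression(
    design: pd.DataFrame,
    outcome: np.ndarray,
    start_vars: list[str],
    candidate_vars: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    max_steps: int = 200,
) -> StepwiseTrace:
    """Forward-backward stepwise OLS starting from the derived measures.

    Each forward step adds the candidate with the smallest entry p-value
    below ``p_enter``; a backward pass then drops any current variable
    (start variables included) whose p-value exceeds ``p_remove``,
    recording which addition triggered the drop.  Terminates when no move
    applies.
    """
    y = np.asarray(outcome, float)
    overlap = set(start_vars) & set(candidate_vars)
    if overlap:
        raise InvalidConfigError(f"candidates overlap the start set: {sorted(overlap)}")
    current = list(start_vars)
    remaining = list(candidate_vars)
    trace = StepwiseTrace()
    _, trace.start_r2 = _ols_pvalues(design[current], y)

    for _ in range(max_steps):
        best_var, best_p = None, p_enter
        for cand in remaining:
            pvals, _ = _ols_pvalues(design[current + [cand]], y)
            if pvals[cand] < best_p:
                best_var, best_p = cand, pvals[cand]
        if best_var is None:
            break
        current.append(best_var)
        remaining.remove(best_var)
        pvals, r2 = _ols_pvalues(design[current], y)
        trace.steps.append(
            {"action": "add", "variable": best_var, "p_value": float(best_p), "r2": r2}
        )
        while True:
            pvals, r2 = _ols_pvalues(design[current], y)
            worst = pvals.idxmax()
            if pvals[worst] <= p_remove or len(current) <= 1:
                break
            current.remove(worst)
            trace.steps.append(
                {
                    "action": "drop",
                    "variable": worst,
                    "p_value": float(pvals[worst]),
                    "r2": _ols_pvalues(design[current], y)[1],
                    "triggered_by": best_var,
                }
            )
    trace.final_variables = list(current)
    return trace
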
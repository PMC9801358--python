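"""Tract filtering, cross-validation, the baseline-vs-test report, and
stepwise regression."""

import numpy as np
import pandas as pd
import pytest

from neighvisit import (
    ModelSpec,
    SimulationConfig,
    aggregate_importance,
    cross_validate,
    filter_tracts,
    run_baseline_and_test,
    simulate_study,
    stepwise_regression,
)
from neighvisit.comparison import _improvement
from neighvisit.errors import EmptyAnalysisError, InvalidConfigError, SchemaError


class TestFilterTracts:
    def test_both_rules_fire(self):
        tracts = pd.DataFrame(
            {
                "tract_id": ["a", "b"],
                "population": [40, 60],
                "obesity_prevalence": [20.0, np.nan],
            }
        )
        with pytest.raises(EmptyAnalysisError):
            filter_tracts(tracts)

    def test_population_exactly_at_floor_retained(self):
        tracts = pd.DataFrame(
            {
                "tract_id": ["a", "b"],
                "population": [50, 49],
                "obesity_prevalence": [20.0, 21.0],
            }
        )
        kept, info = filter_tracts(tracts)
        assert list(kept["tract_id"]) == ["a"]
        assert info["n_excluded"] == 1
        assert info["pct_excluded"] == pytest.approx(50.0)

    def test_no_exclusions_identity(self):
        tracts = pd.DataFrame(
            {
                "tract_id": ["a", "b"],
                "population": [100, 200],
                "obesity_prevalence": [20.0, 25.0],
            }
        )
        kept, info = filter_tracts(tracts)
        assert len(kept) == 2 and info["n_excluded"] == 0

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError):
            filter_tracts(pd.DataFrame({"tract_id": ["a"]}))


class TestCrossValidate:
    def test_folds_partition_indices(self):
        from sklearn.model_selection import KFold

        seen = np.zeros(53, dtype=int)
        for _, test in KFold(10, shuffle=True, random_state=0).split(np.arange(53)):
            seen[test] += 1
        assert (seen == 1).all()

    def test_cv_r2_matches_theory(self):
        """Var(signal) = 3 sigma^2 gives population R^2 = 0.75."""
        rng = np.random.default_rng(17)
        n = 5000
        design = pd.DataFrame({"x": rng.normal(size=n)})
        y = np.sqrt(3.0) * design["x"].to_numpy() + rng.normal(size=n)
        res = cross_validate(ModelSpec(kind="ols"), design, y, k=10, seed=1)
        assert res["r2"] == pytest.approx(0.75, abs=0.05)

    def test_k_larger_than_n_rejected(self, rng):
        design = pd.DataFrame({"x": rng.normal(size=5)})
        with pytest.raises(InvalidConfigError):
            cross_validate(ModelSpec(kind="ols"), design, rng.normal(size=5), k=10)

    def test_same_seed_identical_metrics(self, rng):
        design = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = design["a"].to_numpy() + rng.normal(size=120)
        spec = ModelSpec(kind="rf", seed=4, n_trees=40)
        a = cross_validate(spec, design, y, k=5, seed=9)
        b = cross_validate(spec, design, y, k=5, seed=9)
        assert a == b


class TestAggregateImportance:
    def test_idempotent_on_identical_folds(self):
        fold = {"a": 0.6, "b": 0.3, "c": 0.1}
        out = aggregate_importance([fold] * 10).set_index("variable")
        assert out.loc["a", "mean_importance"] == pytest.approx(0.6)
        assert list(out.index) == ["a", "b", "c"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_means_sum_to_one(self, rng):
        folds = []
        for _ in range(10):
            w = rng.dirichlet([2, 2, 2])
            folds.append({"a": w[0], "b": w[1], "c": w[2]})
        out = aggregate_importance(folds)
        assert out["mean_importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_inconsistent_sets_rejected(self):
        with pytest.raises(SchemaError):
            aggregate_importance([{"a": 1.0}, {"b": 1.0}])


class TestRunBaselineAndTest:
    @pytest.fixture(scope="class")
    def study(self):
        cfg = SimulationConfig(n_tracts=300, seed=4)
        study = simulate_study(cfg)
        tracts, _ = filter_tracts(study["tracts"])
        return study, tracts

    def test_report_shape_and_conventions(self, study):
        """Five models x two sets; statistical models carry in-sample
        adjusted R2/AIC, machine-learning models carry CV metrics only."""
        full, tracts = study
        baseline = ["pct_black", "pct_hispanic", "median_home_value",
                    "pct_unemployment", "population_density"]
        specs = [
            ModelSpec(kind="ols"),
            ModelSpec(kind="gwr", bandwidth=len(tracts)),
            ModelSpec(kind="rf", n_trees=50),
            ModelSpec(kind="dnn"),
            ModelSpec(kind="grf", n_trees=40, n_local_neighbors=60, local_n_trees=20),
        ]
        report = run_baseline_and_test(
            tracts, full["true_measures"], baseline, specs, seed=1, k_folds=5
        )
        assert set(report.cells) == {"ols", "gwr", "rf", "dnn", "grf"}
        for kind, sets in report.cells.items():
            assert set(sets) == {"baseline", "test"}
            for metrics in sets.values():
                assert "error" not in metrics
                if kind in ("ols", "gwr"):
                    assert {"r2", "rmse", "adjusted_r2", "aic"} <= set(metrics)
                else:
                    assert set(metrics) == {"r2", "rmse"}
        assert report.test_variables == baseline + [
            "fast_food_vf", "fitness_vf", "nature_park_vf"
        ]

    def test_dnn_failure_recorded_not_raised(self, study):
        full, tracts = study
        small = tracts.head(77)
        baseline = ["pct_black", "median_home_value"]
        report = run_baseline_and_test(
            small, full["true_measures"], baseline,
            [ModelSpec(kind="ols"), ModelSpec(kind="dnn")], seed=0, k_folds=5,
        )
        assert "error" in report.cells["dnn"]["baseline"]
        assert "SampleSizeError" in report.cells["dnn"]["baseline"]["error"]
        assert "error" not in report.cells["ols"]["baseline"]

    def test_tie_flagging_at_three_decimals(self):
        assert _improvement("r2", 0.9341, 0.9342) == "tie"
        assert _improvement("r2", 0.934, 0.936) == "improved"
        assert _improvement("rmse", 1.10, 1.20) == "worse"
        assert _improvement("aic", 100.0, 90.0) == "improved"


class TestExperimentLogic:
    def test_behavior_coupling_improves_ols(self):
        """With the visit frequencies truly in the outcome, the test set
        beats baseline OLS R2 in nearly every seed."""
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(n_tracts=300, seed=seed)
            study = simulate_study(cfg)
            tracts, _ = filter_tracts(study["tracts"])
            baseline = ["pct_black", "pct_hispanic", "pct_married",
                        "median_home_value", "pct_unemployment"]
            report = run_baseline_and_test(
                tracts, study["true_measures"], baseline,
                [ModelSpec(kind="ols")], seed=seed,
            )
            cells = report.cells["ols"]
            wins += cells["test"]["r2"] > cells["baseline"]["r2"]
        assert wins >= 9

    def test_zero_coupling_no_improvement(self):
        """Decoupled visit frequencies add nothing: tiny R2 gap and AIC
        favoring the baseline on average."""
        gaps, aic_deltas = [], []
        for seed in range(5):
            coefs = {"pct_below_poverty": 0.5, "median_income": -0.3,
                     "pct_age_60_plus": 0.1}
            cfg = SimulationConfig(
                n_tracts=300, seed=seed, true_coefficients=coefs,
                behavior_disadvantage_loading=0.0,
            )
            study = simulate_study(cfg)
            tracts, _ = filter_tracts(study["tracts"])
            baseline = ["pct_below_poverty", "median_income", "pct_age_60_plus",
                        "pct_black", "pct_married"]
            report = run_baseline_and_test(
                tracts, study["true_measures"], baseline,
                [ModelSpec(kind="ols")], seed=seed,
            )
            cells = report.cells["ols"]
            gaps.append(abs(cells["test"]["r2"] - cells["baseline"]["r2"]))
            aic_deltas.append(cells["test"]["aic"] - cells["baseline"]["aic"])
        assert all(g < 0.02 for g in gaps)
        assert np.mean(aic_deltas) > 0


class TestStepwise:
    def design(self, rng, n=600):
        cols = {f"noise{i}": rng.normal(size=n) for i in range(5)}
        cols["A"] = rng.normal(size=n)
        cols["m1"] = rng.normal(size=n)
        cols["m2"] = rng.normal(size=n)
        cols["m3"] = rng.normal(size=n)
        return pd.DataFrame(cols)

    def test_empty_candidates_returns_start_model(self, rng):
        design = self.design(rng)
        y = design["m1"].to_numpy() + rng.normal(size=len(design))
        trace = stepwise_regression(design, y, ["m1", "m2", "m3"], [])
        assert trace.steps == []
        assert trace.final_variables == ["m1", "m2", "m3"]

    def test_selection_consistency(self):
        """Truth = {m1, A}: the final model keeps both and rejects noise in
        a majority of seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            design = self.design(rng, n=2000)
            y = (
                0.6 * design["m1"].to_numpy()
                + 0.5 * design["A"].to_numpy()
                + rng.normal(size=2000)
            )
            trace = stepwise_regression(
                design, y, ["m1", "m2", "m3"],
                ["A"] + [f"noise{i}" for i in range(5)],
            )
            final = set(trace.final_variables)
            hits += {"m1", "A"} <= final and not any(
                v.startswith("noise") for v in final
            )
        assert hits >= 6

    def test_redundant_measure_dropped_after_proxy_enters(self):
        """m3 is a noisy proxy of candidate B; once B enters, m3 loses
        significance and is dropped -- the redundancy pattern."""
        rng = np.random.default_rng(1)
        n = 1500
        b = rng.normal(size=n)
        m3 = 0.9 * b + np.sqrt(1 - 0.81) * rng.normal(size=n)
        design = pd.DataFrame(
            {
                "m1": rng.normal(size=n),
                "m2": rng.normal(size=n),
                "m3": m3,
                "B": b,
                "other": rng.normal(size=n),
            }
        )
        y = 0.8 * b + 0.4 * design["m1"].to_numpy() + rng.normal(size=n)
        trace = stepwise_regression(design, y, ["m1", "m2", "m3"], ["B", "other"])
        drops = [s for s in trace.steps if s["action"] == "drop"]
        assert any(s["variable"] == "m3" and s["triggered_by"] == "B" for s in drops)
        assert "m3" not in trace.final_variables
        assert "B" in trace.final_variables

    def test_trace_replay_reproduces_final_model(self, rng):
        design = self.design(rng, n=800)
        y = 0.5 * design["A"].to_numpy() + rng.normal(size=800)
        trace = stepwise_regression(
            design, y, ["m1", "m2", "m3"], ["A", "noise0", "noise1"]
        )
        replayed = ["m1", "m2", "m3"]
        for step in trace.steps:
            if step["action"] == "add":
                replayed.append(step["variable"])
            else:
                replayed.remove(step["variable"])
        assert replayed == trace.final_variables
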
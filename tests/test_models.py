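"""The five estimators: exact limits, oracle equivalence, recovery, and
determinism."""

import numpy as np
import pandas as pd
import pytest

from neighvisit import (
    ModelSpec,
    fit_dnn,
    fit_grf,
    fit_gwr,
    fit_model,
    fit_ols,
    fit_rf,
    golden_section_bandwidth,
)
from neighvisit.errors import InvalidConfigError, SampleSizeError, SingularDesignError
from neighvisit.models import gwr_aicc, significance_stars


def linear_data(n, betas, noise_sd, seed, extent=10.0):
    rng = np.random.default_rng(seed)
    design = pd.DataFrame(
        rng.normal(size=(n, len(betas))), columns=[f"x{i}" for i in range(len(betas))]
    )
    coords = rng.uniform(0, extent, (n, 2))
    y = design.to_numpy() @ np.asarray(betas) + noise_sd * rng.normal(size=n)
    return design, y, coords


class TestOls:
    def test_exact_interpolation(self):
        design = pd.DataFrame({"x1": np.linspace(-2, 2, 30)})
        y = 2.0 * design["x1"].to_numpy() + 1.0
        res = fit_ols(design, y)
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert res.metrics["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_null_signal(self):
        design, y, _ = linear_data(10_000, [0.0, 0.0], 1.0, seed=3)
        res = fit_ols(design, y)
        assert res.metrics["r2"] < 0.01

    def test_parameter_recovery(self):
        design, y, _ = linear_data(2000, [0.8, -0.5, 0.0], 1.0, seed=5)
        res = fit_ols(design, y)
        oracle = np.linalg.solve(
            *(lambda a: (a.T @ a, a.T @ y))(
                np.column_stack([np.ones(2000), design.to_numpy()])
            )
        )
        for i, truth in enumerate([0.8, -0.5, 0.0]):
            est = res.coefficients[f"x{i}"]
            assert est == pytest.approx(truth, abs=0.1)
            assert est == pytest.approx(oracle[i + 1], abs=1e-10)

    def test_rank_deficient_rejected(self, rng):
        a = rng.normal(size=50)
        design = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(SingularDesignError):
            fit_ols(design, rng.normal(size=50))

    def test_significance_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""

    def test_aic_penalizes_noise_variable(self):
        """Adding a truly active variable lowers AIC; adding pure noise
        raises it in expectation across seeds."""
        deltas_signal, deltas_noise = [], []
        for seed in range(8):
            design, y, _ = linear_data(1500, [0.6, 0.4], 1.0, seed=seed)
            reduced = fit_ols(design[["x0"]], y).metrics["aic"]
            full = fit_ols(design, y).metrics["aic"]
            deltas_signal.append(full - reduced)
            rng = np.random.default_rng(seed + 100)
            noisy = design.assign(junk=rng.normal(size=1500))
            deltas_noise.append(fit_ols(noisy, y).metrics["aic"] - full)
        assert all(d < 0 for d in deltas_signal)
        assert np.mean(deltas_noise) > 0


class TestGwr:
    def test_uniform_full_bandwidth_equals_ols(self):
        design, y, coords = linear_data(120, [0.7, -0.3], 0.5, seed=2)
        ols = fit_ols(design, y)
        gwr = fit_gwr(design, y, coords, bandwidth=120, kernel="uniform")
        for name in ["intercept", "x0", "x1"]:
            col = gwr.local_coefficients[name].to_numpy()
            assert np.allclose(col, ols.coefficients[name], atol=1e-8)

    def test_in_sample_r2_at_least_ols(self):
        design, y, coords = linear_data(150, [0.5, 0.2], 1.0, seed=4)
        ols = fit_ols(design, y)
        gwr = fit_gwr(design, y, coords, bandwidth=60)
        assert gwr.metrics["r2"] >= ols.metrics["r2"] - 1e-10

    def test_coefficient_surface_recovery(self):
        """A west-east linear coefficient gradient is recovered with
        correlation > 0.8 at n=400."""
        rng = np.random.default_rng(11)
        n, extent = 400, 10.0
        coords = rng.uniform(0, extent, (n, 2))
        design = pd.DataFrame({"x0": rng.normal(size=n), "x1": rng.normal(size=n)})
        true_beta = coords[:, 0] / extent
        y = (
            1.0
            + true_beta * design["x0"].to_numpy()
            + 0.3 * design["x1"].to_numpy()
            + 0.1 * rng.normal(size=n)
        )
        res = fit_gwr(design, y, coords, bandwidth=80)
        est = res.local_coefficients["x0"].to_numpy()
        assert np.corrcoef(est, true_beta)[0, 1] > 0.8

    def test_bandwidth_floor(self):
        design, y, coords = linear_data(50, [0.5], 0.5, seed=6)
        with pytest.raises(InvalidConfigError):
            fit_gwr(design, y, coords, bandwidth=2)


class TestGoldenSectionBandwidth:
    def grid_oracle(self, design, y, coords):
        import math

        from neighvisit.models import _gwr_solve

        x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
        dist = np.hypot(
            coords[:, None, 0] - coords[None, :, 0],
            coords[:, None, 1] - coords[None, :, 1],
        )
        scores = {}
        for bw in range(x.shape[1] + 1, len(y) + 1):
            _, fitted, tr_s = _gwr_solve(x, y, dist, bw, "bisquare")
            scores[bw] = gwr_aicc(float(((y - fitted) ** 2).sum()), len(y), tr_s)
        return scores

    def test_matches_exhaustive_grid(self):
        design, y, coords = linear_data(100, [0.6, -0.4], 0.8, seed=9)
        bw = golden_section_bandwidth(design, y, coords)
        scores = self.grid_oracle(design, y, coords)
        best = min(scores.values())
        assert scores[bw] <= best + abs(best) * 1e-3 + 0.5

    def test_global_process_prefers_large_bandwidth(self):
        design, y, coords = linear_data(100, [0.8, 0.3], 0.5, seed=10)
        bw = golden_section_bandwidth(design, y, coords)
        lo, hi = design.shape[1] + 2, len(y)
        assert bw >= lo + 0.75 * (hi - lo)

    def test_local_process_prefers_small_bandwidth(self):
        rng = np.random.default_rng(13)
        n, extent = 150, 10.0
        coords = rng.uniform(0, extent, (n, 2))
        design = pd.DataFrame({"x0": rng.normal(size=n)})
        beta = np.sin(2 * np.pi * coords[:, 0] / extent) * 2.0
        y = beta * design["x0"].to_numpy() + 0.1 * rng.normal(size=n)
        bw = golden_section_bandwidth(design, y, coords)
        lo, hi = design.shape[1] + 2, n
        assert bw < (lo + hi) / 2


class TestRf:
    def test_importances_sum_to_one(self, rng):
        design = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        y = design["a"].to_numpy() + 0.2 * rng.normal(size=300)
        res = fit_rf(design, y, ModelSpec(kind="rf", seed=0, n_trees=100))
        assert sum(res.importances.values()) == pytest.approx(1.0, abs=1e-9)

    def test_informative_feature_ranks_first(self):
        """One informative + five noise features: the informative one gets
        the top importance in nearly every seed."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            design = pd.DataFrame(
                rng.normal(size=(2000, 6)), columns=[f"f{i}" for i in range(6)]
            )
            y = design["f0"].to_numpy() + 0.5 * rng.normal(size=2000)
            res = fit_rf(design, y, ModelSpec(kind="rf", seed=seed, n_trees=60))
            wins += max(res.importances, key=res.importances.get) == "f0"
        assert wins >= 9

    def test_seeded_determinism(self, rng):
        design = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = rng.normal(size=200)
        a = fit_rf(design, y, ModelSpec(kind="rf", seed=5, n_trees=50))
        b = fit_rf(design, y, ModelSpec(kind="rf", seed=5, n_trees=50))
        np.testing.assert_array_equal(a.fitted, b.fitted)

    def test_zero_trees_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            ModelSpec(kind="rf", n_trees=0)


class TestGrf:
    def test_degenerates_to_global_rf(self):
        rng = np.random.default_rng(3)
        n = 80
        design = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = design["a"].to_numpy() + 0.3 * rng.normal(size=n)
        coords = rng.uniform(0, 5, (n, 2))
        spec = ModelSpec(kind="grf", seed=1, n_trees=50, n_local_neighbors=n,
                         blend_weight=1.0)
        grf = fit_grf(design, y, coords, spec)
        rf = fit_rf(design, y, ModelSpec(kind="rf", seed=1, n_trees=50))
        np.testing.assert_array_equal(grf.fitted, rf.fitted)

    def test_west_east_split_signal(self):
        """Feature A drives the outcome in the west half, B in the east:
        mean local importance of A is higher in the west."""
        successes = 0
        n = 800
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 10, (n, 2))
            west = coords[:, 0] < 5
            design = pd.DataFrame(
                {"A": rng.normal(size=n), "B": rng.normal(size=n),
                 "C": rng.normal(size=n)}
            )
            y = np.where(
                west,
                2.0 * design["A"].to_numpy(),
                2.0 * design["B"].to_numpy(),
            ) + 0.3 * rng.normal(size=n)
            spec = ModelSpec(kind="grf", seed=seed, n_trees=30,
                             n_local_neighbors=60, local_n_trees=20)
            res = fit_grf(design, y, coords, spec)
            imp_a = res.local_importances["A"].to_numpy()
            successes += imp_a[west].mean() > imp_a[~west].mean()
        assert successes >= 9

    def test_neighbor_count_bounds(self, rng):
        design = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = rng.normal(size=50)
        coords = rng.uniform(0, 5, (50, 2))
        with pytest.raises(InvalidConfigError):
            fit_grf(design, y, coords, ModelSpec(kind="grf", n_local_neighbors=51))
        with pytest.raises(InvalidConfigError):
            fit_grf(design, y, coords, ModelSpec(kind="grf", n_local_neighbors=10))

    def test_blend_continuity_and_determinism(self):
        rng = np.random.default_rng(8)
        n = 120
        design = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = design["a"].to_numpy() + 0.5 * rng.normal(size=n)
        coords = rng.uniform(0, 5, (n, 2))
        preds = {}
        for w in (0.0, 0.5, 1.0):
            spec = ModelSpec(kind="grf", seed=2, n_trees=40, n_local_neighbors=40,
                             local_n_trees=20, blend_weight=w)
            preds[w] = fit_grf(design, y, coords, spec).fitted
        mid = 0.5 * preds[0.0] + 0.5 * preds[1.0]
        np.testing.assert_allclose(preds[0.5], mid, atol=1e-10)
        spec = ModelSpec(kind="grf", seed=2, n_trees=40, n_local_neighbors=40,
                         local_n_trees=20)
        again = fit_grf(design, y, coords, spec).fitted
        np.testing.assert_array_equal(preds[0.5], again)


class TestDnn:
    def test_small_sample_refused(self, rng):
        design = pd.DataFrame(rng.normal(size=(77, 4)), columns=list("abcd"))
        with pytest.raises(SampleSizeError):
            fit_dnn(design, rng.normal(size=77), ModelSpec(kind="dnn"))

    def test_linear_truth_close_to_ols(self):
        design, y, _ = linear_data(2000, [0.8, -0.5, 0.3], 0.5, seed=21)
        ols = fit_ols(design, y)
        dnn = fit_dnn(design, y, ModelSpec(kind="dnn", seed=0))
        assert abs(dnn.metrics["r2"] - ols.metrics["r2"]) < 0.1

    def test_seeded_determinism(self):
        design, y, _ = linear_data(300, [0.5, 0.2], 0.5, seed=22)
        a = fit_dnn(design, y, ModelSpec(kind="dnn", seed=3))
        b = fit_dnn(design, y, ModelSpec(kind="dnn", seed=3))
        assert abs(a.metrics["r2"] - b.metrics["r2"]) <= 1e-6


def test_dispatch_rejects_unknown_kind():
    with pytest.raises(InvalidConfigError):
        ModelSpec(kind="svm")


def test_gwr_requires_coords(rng):
    design = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
    with pytest.raises(InvalidConfigError):
        fit_model(ModelSpec(kind="gwr"), design, rng.normal(size=50), None)
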
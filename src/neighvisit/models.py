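"""The five estimators under one fit/predict/summarize contract.

* **OLS** -- global linear model (statsmodels), coefficient p-values with
  the conventional significance stars (* < 0.05, ** < 0.01, *** < 0.001).
* **GWR** -- geographically weighted regression: one weighted least-squares
  fit per tract with an adaptive bisquare kernel
  ``w = (1 - (d/d_max)^2)^2`` inside the bandwidth (the distance to the
  bandwidth-th nearest neighbor), zero outside.  The bandwidth is chosen
  by golden-section search of the corrected AIC
  ``AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S))``
  where S is the hat matrix and tr(S) the effective number of parameters.
* **RF** -- a seeded random-forest regressor (scikit-learn) with impurity
  importances normalized to sum to 1.
* **GRF** -- geographical random forests: a global forest plus one local
  forest per tract trained on its nearest neighbors; predictions blend
  the two, and per-location local importances are retained.
* **DNN** -- a small feed-forward network (seeded, early stopping) with a
  fixed architecture grid of {1, 2} hidden layers x {16, 32, 64} widths;
  it refuses to train below 100 observations, the failure mode seen on
  very small cities.

All designs are expected standardized; coordinates are planar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .errors import InvalidConfigError, SampleSizeError, SingularDesignError

MODEL_KINDS = ("ols", "gwr", "rf", "dnn", "grf")

DNN_SAMPLE_FLOOR = 100
DNN_GRID = [(16,), (32,), (64,), (16, 16), (32, 32), (64, 64)]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ModelSpec:
    """Which estimator to fit and with what hyperparameters."""

    kind: str = "ols"
    seed: int = 0
    # gwr
    bandwidth: int | str = "auto"
    kernel: str = "bisquare"
    criterion: str = "aicc"
    # rf (also the global/local forests of grf)
    n_trees: int = 200
    max_depth: int | None = None
    min_leaf: int = 1
    # grf
    n_local_neighbors: int = 100
    blend_weight: float = 0.5
    local_n_trees: int = 30
    eager_locals: bool = True  # False: train local forests only where predictions are requested
    # dnn
    epochs: int = 400
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise InvalidConfigError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.blend_weight <= 1.0:
            raise InvalidConfigError("blend_weight must lie in [0, 1]")
        if self.n_trees < 1 or self.local_n_trees < 1:
            raise InvalidConfigError("forests need at least one tree")
        if self.kernel not in ("bisquare", "uniform"):
            raise InvalidConfigError("kernel must be 'bisquare' or 'uniform'")


@dataclass
class ModelResult:
    """Fitted-model summary shared by all five estimators."""

    kind: str
    metrics: dict[str, float]
    coefficients: dict[str, float] | None = None
    std_errors: dict[str, float] | None = None
    p_values: dict[str, float] | None = None
    stars: dict[str, str] | None = None
    importances: dict[str, float] | None = None
    local_coefficients: pd.DataFrame | None = None
    local_importances: pd.DataFrame | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    bandwidth: int | None = None
    effective_parameters: float | None = None
    extras: dict = field(default_factory=dict)

    def predict(self, design: pd.DataFrame, coords: np.ndarray | None = None):
        fn = self.extras.get("predict_fn")
        if fn is None:
            raise InvalidConfigError(f"{self.kind} result does not support predict")
        return fn(design, coords)


# ---------------------------------------------------------------- OLS


def fit_ols(design: pd.DataFrame, outcome: np.ndarray, spec: ModelSpec | None = None) -> ModelResult:
    """Global linear model with intercept on a standardized design."""
    y = np.asarray(outcome, dtype=float)
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise SampleSizeError(f"need n > p + 1 (n={n}, p={p})")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise InvalidConfigError("design/outcome contain non-finite values")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p + 1:
        raise SingularDesignError("design matrix is rank deficient")
    exog = sm.add_constant(design.to_numpy(float), has_constant="add")
    fit = sm.OLS(y, exog).fit()
    names = ["intercept", *design.columns]
    coefs = dict(zip(names, fit.params))
    pvals = dict(zip(names, fit.pvalues))
    resid = y - fit.fittedvalues
    return ModelResult(
        kind="ols",
        metrics={
            "r2": float(fit.rsquared),
            "adjusted_r2": float(fit.rsquared_adj),
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "aic": float(fit.aic),
        },
        coefficients=coefs,
        std_errors=dict(zip(names, fit.bse)),
        p_values=pvals,
        stars={k: significance_stars(v) for k, v in pvals.items()},
        fitted=np.asarray(fit.fittedvalues),
        residuals=resid,
        extras={
            "predict_fn": lambda d, c=None, b=np.asarray(fit.params): np.column_stack(
                [np.ones(len(d)), d.to_numpy(float)]
            )
            @ b
        },
    )


# ---------------------------------------------------------------- GWR


def _bisquare_weights(d: np.ndarray, dmax: float) -> np.ndarray:
    w = np.zeros_like(d)
    inside = d < dmax
    if dmax > 0:
        w[inside] = (1.0 - (d[inside] / dmax) ** 2) ** 2
    else:  # all points coincide with the focal point
        w[inside] = 1.0
    return w


def _gwr_solve(
    x: np.ndarray,
    y: np.ndarray,
    dist: np.ndarray,
    bandwidth: int,
    kernel: str,
    need_hat: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Local WLS at every row. Returns (betas, fitted, trace_S)."""
    n, p1 = x.shape
    betas = np.empty((n, p1))
    fitted = np.empty(n)
    tr_s = 0.0
    order = np.argsort(dist, axis=1)
    for i in range(n):
        d = dist[i]
        # adaptive bandwidth: distance to the bandwidth-th nearest neighbor
        # (the focal point itself is row i with d=0, hence index bandwidth-1)
        dmax = d[order[i, min(bandwidth, n) - 1]]
        if kernel == "uniform":
            w = (d <= dmax).astype(float)
        else:
            w = _bisquare_weights(d, dmax)
            w[i] = 1.0  # focal point always gets full weight
        xw = x * w[:, None]
        xtwx = x.T @ xw
        xtwy = xw.T @ y
        try:
            m = np.linalg.solve(xtwx, np.eye(p1))
        except np.linalg.LinAlgError:
            m = np.linalg.solve(xtwx + 1e-8 * np.eye(p1), np.eye(p1))
        if not np.all(np.isfinite(m)):
            m = np.linalg.pinv(xtwx + 1e-8 * np.eye(p1))
        beta = m @ xtwy
        betas[i] = beta
        fitted[i] = x[i] @ beta
        if need_hat:
            # hat row r = x_i (X'WX)^-1 X'W; only the diagonal entry is needed
            tr_s += float(x[i] @ m @ (x[i] * w[i]))
    return betas, fitted, tr_s


def gwr_aicc(rss: float, n: int, tr_s: float) -> float:
    denom = n - 2.0 - tr_s
    # near-interpolating bandwidths (rss ~ 0 or tr(S) ~ n) are rejected:
    # the corrected-AIC formula is undefined there
    if denom <= 1.0 or rss <= n * 1e-12 or not math.isfinite(rss):
        return math.inf
    sigma = math.sqrt(rss / n)
    return 2.0 * n * math.log(sigma) + n * math.log(2 * math.pi) + n * (n + tr_s) / denom


def _gwr_cv_score(x, y, dist, bandwidth, kernel) -> float:
    """Leave-one-out CV score: each local fit downweights the focal point
    to zero and predicts it."""
    n, p1 = x.shape
    order = np.argsort(dist, axis=1)
    press = 0.0
    for i in range(n):
        d = dist[i]
        dmax = d[order[i, min(bandwidth, n) - 1]]
        w = (d <= dmax).astype(float) if kernel == "uniform" else _bisquare_weights(d, dmax)
        w[i] = 0.0
        xw = x * w[:, None]
        xtwx = x.T @ xw
        try:
            beta = np.linalg.solve(xtwx, xw.T @ y)
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(xtwx + 1e-8 * np.eye(p1), xw.T @ y)
        press += (y[i] - x[i] @ beta) ** 2
    return press


def golden_section_bandwidth(
    design: pd.DataFrame,
    outcome: np.ndarray,
    coords: np.ndarray,
    criterion: str = "aicc",
    kernel: str = "bisquare",
    return_trace: bool = False,
):
    """Adaptive bandwidth (neighbor count) minimizing AICc (or LOO-CV) by
    golden-section search over [p + 2, n].

    The search works on integers with memoized evaluations.  If the
    bracket degenerates (non-unimodal criterion), the search falls back to
    a coarse grid scan; either way the returned bandwidth's criterion is
    checked against a final local sweep.
    """
    y = np.asarray(outcome, float)
    x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    n, p1 = x.shape
    if n < 30:
        raise SampleSizeError("bandwidth search needs at least 30 locations")
    dist = np.hypot(
        coords[:, None, 0] - coords[None, :, 0], coords[:, None, 1] - coords[None, :, 1]
    )
    lo, hi = p1 + 1, n
    cache: dict[int, float] = {}
    trace: list[tuple[int, float]] = []

    def score(bw: int) -> float:
        bw = int(min(max(bw, lo), hi))
        if bw not in cache:
            if criterion == "cv":
                val = _gwr_cv_score(x, y, dist, bw, kernel)
            else:
                _, fitted, tr_s = _gwr_solve(x, y, dist, bw, kernel)
                rss = float(((y - fitted) ** 2).sum())
                val = gwr_aicc(rss, n, tr_s)
            cache[bw] = val
            trace.append((bw, val))
        return cache[bw]

    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    while b - a > 1.0:
        if score(round(c)) < score(round(d)):
            b = d
        else:
            a = c
        c = b - phi * (b - a)
        d = a + phi * (b - a)
    best = min(cache, key=cache.get)
    # guard against a non-unimodal criterion: coarse grid fallback
    grid = np.unique(np.linspace(lo, hi, 12).round().astype(int))
    for g in grid:
        score(int(g))
    best = min(cache, key=cache.get)
    if return_trace:
        return best, sorted(trace)
    return best


def fit_gwr(
    design: pd.DataFrame,
    outcome: np.ndarray,
    coords: np.ndarray,
    bandwidth: int | str = "auto",
    kernel: str = "bisquare",
    criterion: str = "aicc",
) -> ModelResult:
    """Geographically weighted regression with adaptive bisquare weights.

    R-squared, adjusted R-squared (using tr(S) as effective parameters),
    RMSE of the per-location fitted values, and the corrected AIC are
    reported; local coefficients are returned per tract.
    """
    y = np.asarray(outcome, float)
    x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    n, p1 = x.shape
    coords = np.asarray(coords, float)
    if not np.all(np.isfinite(coords)):
        raise InvalidConfigError("coordinates must be finite")
    if bandwidth == "auto":
        bandwidth = golden_section_bandwidth(design, y, coords, criterion, kernel)
    bandwidth = int(bandwidth)
    if bandwidth < p1 + 1:
        raise InvalidConfigError(
            f"adaptive bandwidth must be >= number of covariates + 2 (got {bandwidth})"
        )
    dist = np.hypot(
        coords[:, None, 0] - coords[None, :, 0], coords[:, None, 1] - coords[None, :, 1]
    )
    betas, fitted, tr_s = _gwr_solve(x, y, dist, bandwidth, kernel)
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - tr_s - 1) if n - tr_s - 1 > 0 else np.nan
    sigma2 = rss / n
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    names = ["intercept", *design.columns]
    local = pd.DataFrame(betas, columns=names)

    def _predict(new_design: pd.DataFrame, new_coords: np.ndarray):
        nx = np.column_stack([np.ones(len(new_design)), new_design.to_numpy(float)])
        nd = np.hypot(
            new_coords[:, None, 0] - coords[None, :, 0],
            new_coords[:, None, 1] - coords[None, :, 1],
        )
        preds = np.empty(len(nx))
        for i in range(len(nx)):
            d = nd[i]
            dmax = np.partition(d, min(bandwidth, n) - 1)[min(bandwidth, n) - 1]
            w = (d <= dmax).astype(float) if kernel == "uniform" else _bisquare_weights(d, dmax)
            xw = x * w[:, None]
            xtwx = x.T @ xw
            try:
                beta = np.linalg.solve(xtwx, xw.T @ y)
            except np.linalg.LinAlgError:
                beta = np.linalg.solve(xtwx + 1e-8 * np.eye(p1), xw.T @ y)
            preds[i] = nx[i] @ beta
        return preds

    return ModelResult(
        kind="gwr",
        metrics={
            "r2": r2,
            "adjusted_r2": float(adj),
            "rmse": math.sqrt(rss / n),
            "aic": -2.0 * ll + 2.0 * (tr_s + 1.0),
            "aicc": gwr_aicc(rss, n, tr_s),
        },
        local_coefficients=local,
        fitted=fitted,
        residuals=resid,
        bandwidth=bandwidth,
        effective_parameters=tr_s,
        extras={"predict_fn": _predict, "kernel": kernel},
    )


# ---------------------------------------------------------------- RF


def fit_rf(design: pd.DataFrame, outcome: np.ndarray, spec: ModelSpec) -> ModelResult:
    """Seeded random-forest regressor with normalized impurity importances."""
    if spec.n_trees < 1:
        raise InvalidConfigError("n_trees must be >= 1")
    y = np.asarray(outcome, float)
    rf = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_depth=spec.max_depth,
        min_samples_leaf=spec.min_leaf,
        random_state=spec.seed,
        oob_score=len(y) > 50,
        bootstrap=True,
        n_jobs=1,
    )
    rf.fit(design.to_numpy(float), y)
    imp = rf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    fitted = rf.predict(design.to_numpy(float))
    resid = y - fitted
    metrics = {
        "r2": 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum()),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }
    if hasattr(rf, "oob_score_"):
        metrics["oob_r2"] = float(rf.oob_score_)
    return ModelResult(
        kind="rf",
        metrics=metrics,
        importances=dict(zip(design.columns, imp)),
        fitted=fitted,
        residuals=resid,
        extras={"predict_fn": lambda d, c=None: rf.predict(d.to_numpy(float)), "model": rf},
    )


# ---------------------------------------------------------------- GRF


def fit_grf(
    design: pd.DataFrame,
    outcome: np.ndarray,
    coords: np.ndarray,
    spec: ModelSpec,
) -> ModelResult:
    """Geographical random forests.

    A global forest is fitted on all tracts; additionally, for each tract,
    a local forest is fitted on its ``n_local_neighbors`` nearest tracts
    (inclusive of itself).  The prediction at a tract blends the two:
    ``blend_weight * global + (1 - blend_weight) * local``.  For unseen
    locations the local model of the nearest training tract is used.
    Local impurity importances are retained per tract.
    """
    y = np.asarray(outcome, float)
    n = len(y)
    k = spec.n_local_neighbors
    if k > n:
        raise InvalidConfigError(f"n_local_neighbors ({k}) exceeds n_training ({n})")
    if k < 20:
        raise InvalidConfigError("n_local_neighbors must be >= 20")
    coords = np.asarray(coords, float)
    x = design.to_numpy(float)

    global_spec = ModelSpec(kind="rf", seed=spec.seed, n_trees=spec.n_trees,
                            max_depth=spec.max_depth, min_leaf=spec.min_leaf)
    global_res = fit_rf(design, y, global_spec)
    global_rf = global_res.extras["model"]

    dist = np.hypot(
        coords[:, None, 0] - coords[None, :, 0], coords[:, None, 1] - coords[None, :, 1]
    )
    nbr_idx = np.argsort(dist, axis=1)[:, :k]
    local_models: dict[int, RandomForestRegressor] = {}

    def local_model(i: int) -> RandomForestRegressor:
        if i not in local_models:
            rf = RandomForestRegressor(
                n_estimators=spec.local_n_trees,
                max_depth=spec.max_depth,
                min_samples_leaf=spec.min_leaf,
                random_state=spec.seed,
                n_jobs=1,
            )
            idx = nbr_idx[i]
            rf.fit(x[idx], y[idx])
            local_models[i] = rf
        return local_models[i]

    w = spec.blend_weight

    def _predict(new_design: pd.DataFrame, new_coords: np.ndarray):
        nx = new_design.to_numpy(float)
        gp = global_rf.predict(nx)
        nd = np.hypot(
            new_coords[:, None, 0] - coords[None, :, 0],
            new_coords[:, None, 1] - coords[None, :, 1],
        )
        nearest = nd.argmin(axis=1)
        lp = np.array(
            [local_model(nearest[i]).predict(nx[i : i + 1])[0] for i in range(len(nx))]
        )
        return w * gp + (1.0 - w) * lp

    fitted = resid = None
    local_imp_frame = None
    metrics: dict[str, float] = {}
    if spec.eager_locals:
        local_imp = np.empty((n, x.shape[1]))
        local_pred = np.empty(n)
        for i in range(n):
            rf = local_model(i)
            imp = rf.feature_importances_
            s = imp.sum()
            local_imp[i] = imp / s if s > 0 else 1.0 / x.shape[1]
            local_pred[i] = rf.predict(x[i : i + 1])[0]
        fitted = w * global_rf.predict(x) + (1.0 - w) * local_pred
        resid = y - fitted
        metrics = {
            "r2": 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum()),
            "rmse": float(np.sqrt(np.mean(resid**2))),
        }
        local_imp_frame = pd.DataFrame(local_imp, columns=design.columns)

    return ModelResult(
        kind="grf",
        metrics=metrics,
        importances=global_res.importances,
        local_importances=local_imp_frame,
        fitted=fitted,
        residuals=resid,
        extras={"predict_fn": _predict, "global_model": global_rf},
    )


# ---------------------------------------------------------------- DNN


def fit_dnn(design: pd.DataFrame, outcome: np.ndarray, spec: ModelSpec) -> ModelResult:
    """Small feed-forward network with a fixed architecture grid.

    Architectures {1, 2} hidden layers x {16, 32, 64} widths are trained
    with early stopping on an internal validation split; the best
    validation score wins.  The target is z-scored internally and mapped
    back.  Training is refused below 100 observations -- with so few
    records the validation split cannot support architecture selection.
    """
    y = np.asarray(outcome, float)
    n = len(y)
    if n < DNN_SAMPLE_FLOOR:
        raise SampleSizeError(
            f"cannot train the network on {n} records (need >= {DNN_SAMPLE_FLOOR})"
        )
    x = design.to_numpy(float)
    mu, sd = y.mean(), y.std()
    yz = (y - mu) / sd
    best, best_score = None, -np.inf
    for arch in DNN_GRID:
        net = MLPRegressor(
            hidden_layer_sizes=arch,
            learning_rate_init=spec.learning_rate,
            max_iter=spec.epochs,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=20,
            random_state=spec.seed,
        )
        net.fit(x, yz)
        score = net.best_validation_score_
        if score > best_score:
            best, best_score = net, score
    fitted = best.predict(x) * sd + mu
    resid = y - fitted
    return ModelResult(
        kind="dnn",
        metrics={
            "r2": 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum()),
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "validation_r2": float(best_score),
        },
        fitted=fitted,
        residuals=resid,
        extras={
            "predict_fn": lambda d, c=None: best.predict(d.to_numpy(float)) * sd + mu,
            "architecture": best.hidden_layer_sizes,
        },
    )


# ---------------------------------------------------------------- dispatch


def fit_model(
    spec: ModelSpec,
    design: pd.DataFrame,
    outcome: np.ndarray,
    coords: np.ndarray | None = None,
) -> ModelResult:
    """Fit any of the five estimators from a :class:`ModelSpec`."""
    if spec.kind == "ols":
        return fit_ols(design, outcome, spec)
    if spec.kind == "gwr":
        if coords is None:
            raise InvalidConfigError("gwr requires coordinates")
        return fit_gwr(design, outcome, coords, spec.bandwidth, spec.kernel, spec.criterion)
    if spec.kind == "rf":
        return fit_rf(design, outcome, spec)
    if spec.kind == "grf":
        if coords is None:
            raise InvalidConfigError("grf requires coordinates")
        return fit_grf(design, outcome, coords, spec)
    if spec.kind == "dnn":
        return fit_dnn(design, outcome, spec)
    raise InvalidConfigError(f"unknown model kind {spec.kind!r}")
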
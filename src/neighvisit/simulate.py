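"""Synthetic tract / POI / visit / outcome generator.

Emulates the statistical structure of the study's three (proprietary)
inputs with known ground truth:

* **Tracts** -- centroids on a jittered square grid; 24 socioeconomic and
  demographic variables driven by latent factors so that poverty-related
  indicators are strongly correlated and the education and race shares are
  compositional (summing to 100), which is what makes variance-inflation
  diagnostics bite; a resident-device panel size per tract.
* **POIs** -- fast-food restaurants, fitness/sports centers, nature parks,
  scattered over the same extent.
* **Visits** -- per (tract, POI) negative-binomial visitor counts whose
  mean follows a gravity kernel (device count x power-law distance decay)
  scaled by a latent per-tract "behavior" propensity for each category.
  Privacy censoring is applied separately: counts of 1 are dropped and
  counts of 2--4 are recorded as 4.
* **Outcome** -- tract obesity prevalence (percent) from a linear model on
  standardized covariates (optionally with a west-east coefficient
  gradient) plus a simultaneous-autoregressive (SAR) error that induces
  positive spatial autocorrelation.

All draws derive from ``config.seed``; identical configs give bit-identical
outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .config import (
    DEMOGRAPHIC_COLUMNS,
    MEASURE_COLUMNS,
    POI_CATEGORIES,
    SimulationConfig,
)
from .errors import InvalidConfigError, InvalidRecordError
from .spatial import build_weights

LATENT_COLUMNS = tuple(f"_propensity_{c}" for c in POI_CATEGORIES)

CENSOR_THRESHOLD = 4  # counts <= 4 are recorded as 4; counts of 1 are dropped


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _smooth_field(
    xy: np.ndarray, extent: float, rng: np.random.Generator, n_waves: int = 4
) -> np.ndarray:
    """Low-frequency random surface over the extent, standardized."""
    field = np.zeros(len(xy))
    for _ in range(n_waves):
        kx, ky = rng.integers(1, 3, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        field += amp * np.sin(
            2 * np.pi * (kx * xy[:, 0] + ky * xy[:, 1]) / extent + phase
        )
    return (field - field.mean()) / field.std()


def _softmax_shares(logits: np.ndarray) -> np.ndarray:
    """Rows of percentages summing to exactly 100."""
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return 100.0 * e / e.sum(axis=1, keepdims=True)


def generate_tracts(config: SimulationConfig) -> pd.DataFrame:
    """Generate the tract table: centroids, population, device panel size,
    the 24 demographic covariates, and the latent behavior propensities
    (underscore-prefixed columns, excluded from CSV output)."""
    config.validate()
    n = config.n_tracts
    rng = _rng(config, stream=1)

    side = int(np.ceil(np.sqrt(n)))
    cell = config.grid_extent / side
    gi, gj = np.divmod(np.arange(n), side)
    x = (gj + 0.5) * cell + rng.uniform(-0.35, 0.35, n) * cell
    y = (gi + 0.5) * cell + rng.uniform(-0.35, 0.35, n) * cell
    xy = np.column_stack([x, y])

    # Latent factors: disadvantage (spatially smooth + idiosyncratic),
    # urbanicity (radial gradient), age structure.
    smooth = _smooth_field(xy, config.grid_extent, rng)
    disadvantage = 0.9 * smooth + 0.6 * rng.normal(size=n)
    disadvantage /= disadvantage.std()
    center = config.grid_extent / 2.0
    radial = -np.hypot(x - center, y - center)
    urban = 0.7 * (radial - radial.mean()) / radial.std() + 0.7 * rng.normal(size=n)
    age = rng.normal(size=n)

    d, u = disadvantage, urban
    e = lambda s=1.0: s * rng.normal(size=n)  # noqa: E731

    race = _softmax_shares(
        np.column_stack(
            [
                1.2 - 1.0 * d + 0.5 * e(),
                -0.5 + 1.1 * d + 0.7 * e(),
                -3.2 + 0.3 * e(),
                -0.9 + 0.3 * u + 0.8 * e(),
                -3.8 + 0.3 * e(),
                -0.6 + 0.7 * d + 0.7 * e(),
            ]
        )
    )
    edu = _softmax_shares(
        np.column_stack(
            [
                -0.9 + 0.8 * d + 0.3 * e(),
                0.2 + 0.15 * d + 0.2 * e(),
                0.4 - 0.9 * d + 0.3 * e(),
            ]
        )
    )
    ages = _softmax_shares(
        np.column_stack(
            [
                0.1 + 0.25 * u + 0.2 * age + 0.15 * e(),
                0.0 + 0.1 * u + 0.1 * age + 0.15 * e(),
                -0.1 + 0.15 * e(),
                -0.2 - 0.1 * age + 0.15 * e(),
                -0.1 - 0.3 * age + 0.2 * e(),
            ]
        )
    )

    table = pd.DataFrame(
        {
            "tract_id": [f"T{i:05d}" for i in range(n)],
            "x": x,
            "y": y,
        }
    )
    table["pct_white"] = race[:, 0]
    table["pct_black"] = race[:, 1]
    table["pct_native"] = race[:, 2]
    table["pct_asian"] = race[:, 3]
    table["pct_pacific"] = race[:, 4]
    table["pct_hispanic"] = race[:, 5]
    table["pct_male"] = np.clip(48 + 2.0 * e(), 40, 60)
    table["pct_married"] = np.clip(45 - 6.0 * d + 4.0 * e(), 5, 90)
    table["pct_age_18_29"] = ages[:, 0]
    table["pct_age_30_39"] = ages[:, 1]
    table["pct_age_40_49"] = ages[:, 2]
    table["pct_age_50_59"] = ages[:, 3]
    table["pct_age_60_plus"] = ages[:, 4]
    table["pct_less_highschool"] = edu[:, 0]
    table["pct_highschool_no_university"] = edu[:, 1]
    table["pct_university"] = edu[:, 2]
    table["median_income"] = np.clip(65000 - 22000 * d + 8000 * e(), 12000, 250000)
    table["pct_unemployment"] = np.clip(7 + 3.0 * d + 1.5 * e(), 0.2, 40)
    table["pct_below_poverty"] = np.clip(18 + 9.0 * d + 2.5 * e(), 0.5, 70)
    table["pct_food_stamp"] = np.clip(15 + 8.0 * d + 2.5 * e(), 0.5, 65)
    table["median_home_value"] = np.clip(
        280000 - 90000 * d + 40000 * u + 50000 * e(), 40000, 2_000_000
    )
    table["median_year_built"] = np.clip(1955 + 8.0 * u + 15.0 * e(), 1880, 2020)
    table["pct_renter_occupied"] = np.clip(45 + 10.0 * u + 6.0 * d + 8.0 * e(), 3, 98)
    table["population_density"] = 3000.0 * np.exp(0.5 * u + 0.3 * e())

    population = np.round(np.exp(8.2 + 0.45 * rng.normal(size=n))).astype(int)
    low = rng.random(n) < config.low_pop_fraction
    population[low] = rng.integers(5, 50, size=low.sum())
    table["population"] = population
    devices = rng.poisson(
        config.mean_devices_per_tract * np.clip(population, 30, None) / 3650.0
    )
    table["device_count"] = np.maximum(devices, 1)

    # Latent behavior propensities: the same disadvantage factor that shapes
    # demographics also shapes place visits (fast food up, fitness/parks
    # down), plus smooth spatial variation and idiosyncratic taste.
    load = config.behavior_disadvantage_loading
    signs = {"fast_food": 1.0, "fitness": -1.2, "nature_park": -0.6}
    for cat in POI_CATEGORIES:
        prop = (
            signs[cat] * load * d
            + 0.3 * _smooth_field(xy, config.grid_extent, rng)
            + 0.6 * rng.normal(size=n)
        )
        table[f"_propensity_{cat}"] = prop

    table["obesity_prevalence"] = np.nan
    return table


def generate_pois(config: SimulationConfig) -> pd.DataFrame:
    """Generate the POI table (uniform locations over the extent)."""
    config.validate()
    total = sum(config.n_pois_per_category.get(c, 0) for c in POI_CATEGORIES)
    if total < 1:
        raise InvalidConfigError("at least one POI is required")
    rng = _rng(config, stream=2)
    rows = []
    for cat in POI_CATEGORIES:
        m = config.n_pois_per_category.get(cat, 0)
        locs = rng.uniform(0, config.grid_extent, size=(m, 2))
        for j in range(m):
            rows.append((f"P_{cat}_{j:04d}", cat, locs[j, 0], locs[j, 1]))
    return pd.DataFrame(rows, columns=["poi_id", "category", "x", "y"])


def generate_visits(
    tracts: pd.DataFrame, pois: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """True (uncensored) visitor counts for every (tract, POI) pair with a
    nonzero draw.

    The mean count follows a gravity kernel:
    ``intensity * (devices / mean_devices) * exp(propensity_cat) *
    (distance + offset) ** (-gravity_decay)``, and counts are negative
    binomial around it (overdispersion via ``nb_dispersion``), so that the
    privacy censoring at <= 4 removes a realistic share of records.
    """
    config.validate()
    if len(tracts) == 0 or len(pois) == 0:
        raise InvalidConfigError("tracts and pois must be non-empty")
    rng = _rng(config, stream=3)
    txy = tracts[["x", "y"]].to_numpy(float)
    pxy = pois[["x", "y"]].to_numpy(float)
    dist = np.hypot(
        txy[:, None, 0] - pxy[None, :, 0], txy[:, None, 1] - pxy[None, :, 1]
    )
    decay = (dist + config.gravity_offset) ** (-config.gravity_decay)
    devices = tracts["device_count"].to_numpy(float)
    dev_scale = devices / devices.mean()

    frames = []
    size = config.nb_dispersion
    for cat in POI_CATEGORIES:
        sel = (pois["category"] == cat).to_numpy()
        if not sel.any():
            continue
        prop = np.exp(tracts[f"_propensity_{cat}"].to_numpy(float))
        mu = (
            config.visit_intensity
            * dev_scale[:, None]
            * prop[:, None]
            * decay[:, sel]
        )
        # NB(mean mu, size r): p = r / (r + mu)
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
        ti, pj = np.nonzero(counts)
        frames.append(
            pd.DataFrame(
                {
                    "tract_id": tracts["tract_id"].to_numpy()[ti],
                    "poi_id": pois.loc[sel, "poi_id"].to_numpy()[pj],
                    "true_count": counts[ti, pj],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["tract_id", "poi_id", "true_count"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["tract_id", "poi_id"], ignore_index=True)


def apply_censoring(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the privacy rule of the visit panel.

    Counts of 1 are removed entirely; counts of 2--4 are recorded as 4;
    larger counts pass through.  The true count is retained in a separate
    column for validation only (it is never written by the default CSV
    writer).
    """
    if (records["true_count"] < 1).any():
        raise InvalidRecordError("true visit counts must be >= 1")
    kept = records[records["true_count"] >= 2].copy()
    kept["recorded_count"] = np.where(
        kept["true_count"] <= CENSOR_THRESHOLD, CENSOR_THRESHOLD, kept["true_count"]
    ).astype(int)
    return kept.reset_index(drop=True)


def _linear_gradient(x: np.ndarray, extent: float) -> np.ndarray:
    """West-east gradient in [-1, 1] used for spatially varying coefficients."""
    return 2.0 * x / extent - 1.0


def generate_obesity(
    tracts: pd.DataFrame,
    measures: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Fill ``obesity_prevalence`` and return (tracts, ground_truth).

    The linear predictor uses standardized covariates with coefficients
    from ``config.true_coefficients`` (keys may be demographic columns or
    the three visit-frequency measures, which should be the *true*,
    uncensored frequencies so the outcome-behavior coupling is exact).
    When ``spatial_coef_amplitude > 0`` every coefficient is multiplied by
    ``1 + amplitude * g(x)`` with g a west-east linear gradient in [-1, 1].
    The error is SAR: ``(I - rho W)^-1 u`` on row-standardized k-NN
    weights, u ~ N(0, noise_sd^2).  Prevalence is the affine map
    ``outcome_mean + outcome_scale * predictor`` clipped into [0, 100]; a
    configured fraction of tracts gets a missing outcome.
    """
    config.validate()
    n = len(tracts)
    rng = _rng(config, stream=4)
    frame = tracts.merge(measures, on="tract_id", how="left", validate="1:1")
    for c in MEASURE_COLUMNS:
        if c in frame:
            frame[c] = frame[c].fillna(0.0)

    names = list(config.true_coefficients)
    missing = [v for v in names if v not in frame.columns]
    if missing:
        raise InvalidConfigError(
            f"true_coefficients reference variables absent from the design: {missing}"
        )
    eta = np.zeros(n)
    grad = _linear_gradient(frame["x"].to_numpy(float), config.grid_extent)
    local_coefs = {}
    for v in names:
        col = frame[v].to_numpy(float)
        sd = col.std(ddof=1)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        beta = config.true_coefficients[v] * (
            1.0 + config.spatial_coef_amplitude * grad
        )
        local_coefs[v] = beta
        eta += beta * z

    u = rng.normal(scale=config.noise_sd, size=n)
    if config.sar_rho != 0.0 and n > config.sar_knn:
        w = build_weights(tracts, k=config.sar_knn).matrix
        err = spsolve(sparse.eye(n, format="csc") - config.sar_rho * w.tocsc(), u)
    else:
        err = u
    prevalence = np.clip(
        config.outcome_mean + config.outcome_scale * (eta + err), 0.0, 100.0
    )
    drop = rng.random(n) < config.missing_prevalence_fraction
    prevalence = prevalence.astype(float)
    out = tracts.copy()
    out["obesity_prevalence"] = np.where(drop, np.nan, prevalence)

    ground_truth = {
        "true_coefficients": dict(config.true_coefficients),
        "outcome_mean": config.outcome_mean,
        "outcome_scale": config.outcome_scale,
        "sar_rho": config.sar_rho,
        "noise_sd": config.noise_sd,
        "spatial_coef_amplitude": config.spatial_coef_amplitude,
        "coefficient_surface": "1 + amplitude * (2x/extent - 1)",
        "seed": config.seed,
    }
    if config.spatial_coef_amplitude > 0:
        ground_truth["local_coefficients"] = {
            v: local_coefs[v].tolist() for v in names
        }
    return out, ground_truth


def simulate_study(config: SimulationConfig) -> dict:
    """Run the whole generator: tracts, POIs, true + censored visits, true
    visit-frequency measures, outcome.  Returns a dict of artifacts."""
    from .measures import reverse_aggregate, visit_frequency

    tracts = generate_tracts(config)
    pois = generate_pois(config)
    true_visits = generate_visits(tracts, pois, config)
    censored = apply_censoring(true_visits)
    true_records = true_visits.rename(columns={"true_count": "recorded_count"})
    totals = reverse_aggregate(true_records, pois, impute=False)
    true_measures = visit_frequency(totals, tracts)
    tracts, ground_truth = generate_obesity(tracts, true_measures, config)
    return {
        "config": config,
        "tracts": tracts,
        "pois": pois,
        "true_visits": true_visits,
        "visits": censored,
        "true_measures": true_measures,
        "ground_truth": ground_truth,
    }
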
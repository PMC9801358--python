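"""Configuration objects for the synthetic study and the pipeline.

The synthetic generator stands in for three proprietary sources: an
aggregated mobile-device visit panel (tract -> POI visitor counts with
privacy censoring), tract-level adult obesity prevalence, and census
socioeconomic/demographic tables.  :class:`SimulationConfig` fixes the
study conditions -- tract count, POI counts, gravity decay of visits,
strength of the latent behavior signal, and the spatial autocorrelation
of the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

from .errors import InvalidConfigError

POI_CATEGORIES = ("fast_food", "fitness", "nature_park")

#: The three derived place-visit-frequency measures (visitors per resident
#: device, by POI category).
MEASURE_COLUMNS = ("fast_food_vf", "fitness_vf", "nature_park_vf")

#: The 24 tract-level socioeconomic and demographic variables, grouped as
#: (1) race/ethnicity, (2) gender/marital/age, (3) education, (4) economic
#: status, (5) housing condition, (6) urbanicity.
DEMOGRAPHIC_COLUMNS = (
    # race and ethnicity (compositional shares, percent)
    "pct_white",
    "pct_black",
    "pct_native",
    "pct_asian",
    "pct_pacific",
    "pct_hispanic",
    # gender, marital status, age (percent)
    "pct_male",
    "pct_married",
    "pct_age_18_29",
    "pct_age_30_39",
    "pct_age_40_49",
    "pct_age_50_59",
    "pct_age_60_plus",
    # education (compositional shares, percent)
    "pct_less_highschool",
    "pct_highschool_no_university",
    "pct_university",
    # economic status
    "median_income",
    "pct_unemployment",
    "pct_below_poverty",
    "pct_food_stamp",
    # housing condition
    "median_home_value",
    "median_year_built",
    "pct_renter_occupied",
    # urbanicity
    "population_density",
)

EDUCATION_SHARES = (
    "pct_less_highschool",
    "pct_highschool_no_university",
    "pct_university",
)
RACE_SHARES = (
    "pct_white",
    "pct_black",
    "pct_native",
    "pct_asian",
    "pct_pacific",
    "pct_hispanic",
)

#: Variables whose pairwise correlation the latent disadvantage factor keeps
#: high (>= 0.5 in expectation), mirroring real poverty indicators.
POVERTY_VARIABLES = ("pct_below_poverty", "pct_food_stamp")


def _default_coefficients() -> dict[str, float]:
    # Standardized-scale outcome coefficients. Demographic terms dominate;
    # the three visit frequencies carry the extra "behavior" signal whose
    # magnitude is the coupling knob (set them to 0 for the no-improvement
    # regime).
    return {
        "pct_below_poverty": 0.45,
        "median_income": -0.30,
        "pct_less_highschool": 0.25,
        "pct_age_60_plus": 0.10,
        "fast_food_vf": 0.25,
        "fitness_vf": -0.30,
        "nature_park_vf": -0.15,
    }


def _default_pois() -> dict[str, int]:
    return {"fast_food": 60, "fitness": 40, "nature_park": 25}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    Parameters
    ----------
    n_tracts
        Number of census tracts (centroids on a jittered square grid).
    grid_extent
        Side length of the planar study square, in km-like units.
    n_pois_per_category
        POIs to place for each of ``fast_food``, ``fitness``, ``nature_park``.
    gravity_decay
        Power-law distance-decay exponent of the visit gravity kernel.
    mean_devices_per_tract
        Mean resident-device panel size for an average-population tract.
    true_coefficients
        Outcome model coefficients on the standardized scale; keys may name
        any demographic column or one of the three visit-frequency measures.
    spatial_coef_amplitude
        Relative amplitude of the west-east linear gradient multiplying each
        coefficient (0 = globally constant coefficients).
    sar_rho
        Simultaneous-autoregressive parameter of the outcome error, in
        (-1, 1); positive values induce positive spatial autocorrelation.
    noise_sd
        Standard deviation of the innovation driving the SAR error, on the
        standardized linear-predictor scale.
    seed
        Master seed; every stochastic step derives its stream from it.
    """

    n_tracts: int = 900
    grid_extent: float = 30.0
    n_pois_per_category: dict[str, int] = field(default_factory=_default_pois)
    gravity_decay: float = 1.5
    mean_devices_per_tract: float = 150.0
    true_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    spatial_coef_amplitude: float = 0.0
    sar_rho: float = 0.6
    noise_sd: float = 0.5
    seed: int = 0

    # secondary realism knobs (documented defaults, rarely changed)
    nb_dispersion: float = 0.8  # negative-binomial size; smaller = more overdispersed
    visit_intensity: float = 40.0  # base visit rate scale of the gravity kernel
    gravity_offset: float = 1.0  # km added to distances to bound the kernel
    low_pop_fraction: float = 0.03  # tracts below the 50-resident floor
    missing_prevalence_fraction: float = 0.04  # tracts with missing outcome
    behavior_disadvantage_loading: float = 0.5  # propensity ~ disadvantage coupling
    outcome_mean: float = 30.0  # prevalence percent at the average tract
    outcome_scale: float = 8.0  # prevalence percent per unit linear predictor
    sar_knn: int = 8  # k of the k-NN weights used by the SAR error

    def validate(self) -> None:
        if self.n_tracts < 1:
            raise InvalidConfigError("n_tracts must be a positive integer")
        if self.grid_extent <= 0:
            raise InvalidConfigError("grid_extent must be positive")
        unknown = set(self.n_pois_per_category) - set(POI_CATEGORIES)
        if unknown:
            raise InvalidConfigError(f"unknown POI categories: {sorted(unknown)}")
        if any(v < 0 for v in self.n_pois_per_category.values()):
            raise InvalidConfigError("POI counts must be nonnegative")
        if self.gravity_decay < 0:
            raise InvalidConfigError("gravity_decay must be nonnegative")
        if self.mean_devices_per_tract <= 0:
            raise InvalidConfigError("mean_devices_per_tract must be positive")
        if not -1.0 < self.sar_rho < 1.0:
            raise InvalidConfigError("sar_rho must lie strictly inside (-1, 1)")
        if self.spatial_coef_amplitude < 0:
            raise InvalidConfigError("spatial_coef_amplitude must be nonnegative")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        valid_names = set(DEMOGRAPHIC_COLUMNS) | set(MEASURE_COLUMNS)
        bad = set(self.true_coefficients) - valid_names
        if bad:
            raise InvalidConfigError(
                f"true_coefficients name unknown variables: {sorted(bad)}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        cfg = cls(**dict(d))
        cfg.validate()
        return cfg
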
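# Methods

## Data model

The analysis unit is the census tract, represented by its planar centroid
(km-like units, no projection handling — every spatial operation used here
depends only on centroid distances). Each tract carries a population, a
resident-device panel size `S_j`, 24 socioeconomic/demographic covariates
in six groups (race/ethnicity, gender–marital–age, education, economic
status, housing, urbanicity), and an obesity prevalence in percent (0–100,
possibly missing). The visit panel is a list of (tract, POI) pairs with a
recorded visitor count; POIs belong to one of three categories (fast-food
restaurants, fitness/sports centers, nature parks).

Tracts with fewer than 50 residents (strictly fewer: a population of
exactly 50 is retained) or a missing outcome are excluded before analysis,
and the exclusion count and percentage are logged.

## Synthetic generator

The generator stands in for three proprietary sources and is itself
first-class, tested code. What it emulates, and how:

- **Demographics.** A latent "disadvantage" factor (part spatially smooth,
  part idiosyncratic) drives the poverty block (poverty and SNAP shares,
  unemployment, income with negative loading, education), so
  poverty-related indicators are strongly positively correlated. The
  education shares and the six race/ethnicity shares are generated through
  softmax maps and therefore sum to exactly 100 per tract — the
  compositional structure that produces the extreme VIFs the elimination
  cascade exists for. A radial "urbanicity" factor shapes density, renter
  share and home values.
- **Visits.** For each (tract, POI) pair the true visitor count is negative
  binomial (dispersion 0.8) around a gravity mean:
  `intensity · (devices / mean devices) · exp(propensity_cat) ·
  (distance + 1 km)^(−1.5)`. The per-category latent propensity loads on
  the disadvantage factor with signs (+ fast food, − fitness, − parks), so
  the derived measures reproduce the observed correlation pattern with
  obesity. The intensity default (40) puts a large share of counts in the
  1–10 range, where the privacy rules bite: at the default study size
  roughly 45% of true records are single-visitor deletions and ~64% of the
  surviving records are censored 4s.
- **Censoring.** Counts of 1 are dropped; counts of 2–4 are recorded as 4;
  larger counts pass through. True counts are retained in a separate column
  for validation only and are never written by the default CSV writer.
- **Outcome.** Prevalence = 30 + 8 · (linear predictor + SAR error),
  clipped to [0, 100]. The linear predictor uses standardized covariates
  with configured coefficients; keys may be demographic columns or the
  three *true* (uncensored) visit frequencies — the magnitude of the
  visit-frequency coefficients is the behavior-coupling knob, and setting
  them to zero (with the propensity–disadvantage loading zeroed) yields the
  no-improvement regime. The error is simultaneous-autoregressive,
  `(I − ρW)⁻¹u` on row-standardized 8-nearest-neighbor weights with
  ρ = 0.6 by default and `u ~ N(0, 0.5²)`, giving the outcome a global
  Moran's I around 0.5 at the default size. Coefficients can vary in space
  through a west–east linear gradient scaled by `spatial_coef_amplitude`
  (0 by default).

Default study size is 900 tracts (the order of a large city's tract count)
with 60/40/25 POIs per category; 3% of tracts draw a sub-50 population and
4% a missing outcome, so the exclusion stage removes about 7% of tracts.
All draws derive from one master seed through named substreams; identical
configurations give bit-identical outputs.

What the generator does **not** emulate: real polygon geometries and
contiguity, temporal panels, home-tract inference error, non-stationary POI
popularity, and any city-specific magnitudes. Passing tests therefore
demonstrate that the pipeline's logic and estimators behave correctly under
the assumed data-generating structure — not that any particular published
city-level number is recovered; those rest on proprietary inputs.

## Deriving the measures

Reversal aggregates recorded counts per (tract, category) over all POIs.
Imputation replaces each recorded 4 by an independent draw from {2, 3, 4}
with probabilities ∝ k^(−α); α defaults to 2.0 (the human-mobility
literature spans roughly 1.5–2.5) and is exposed in configuration — at
α = 2 the pmf is (0.5902, 0.2623, 0.1475). Draws come from a single seeded
stream taken in record-sorted order, so the derivation is reproducible;
with imputation disabled the stage is fully deterministic. Tracts with no
surviving records receive zero frequencies rather than missing values:
under the data model, absence of recorded visits is informative. The
device-count denominator is treated as a single scalar per tract.

## Spatial statistics

- **Weights:** k-nearest-neighbor (k = 8 by default) on centroid Euclidean
  distance, binary then row-standardized; exact distance ties break by
  tract order. Contiguity weights are impossible on centroid-only data;
  k-NN is the standard geometry-light choice. Arbitrary weights (e.g. rook
  adjacency on a grid) can be supplied directly.
- **Moran's I:** the double-sum formula on mean deviations with
  E[I] = −1/(n−1). Inference is primarily a seeded permutation test
  (999 draws, two-sided around E[I]); a normal approximation from the
  permutation moments is reported alongside, since published work rarely
  states which method produced its p-values.
- **Standardization:** sample standard deviation (n−1), matching mainstream
  statistical software; the transform parameters are returned for exact
  inversion.
- **VIF:** auxiliary regression of each column on all others *with* an
  intercept (the conventional definition; harmless after centering);
  exactly collinear columns report +inf. The cascade removes the single
  highest-VIF variable per round (lexicographic tie-break) until all are
  below the cut-off (5 by default); an ordered `forced_removals` list lets
  a manual published elimination sequence be replayed. Each round strictly
  reduces the dimension, so termination is guaranteed.

## Models

All designs are standardized before fitting; the three derived measures are
standardized together with the covariates by default (a flag disables
this).

- **OLS** (statsmodels): coefficient p-values with significance tiers
  \*p<0.05, \*\*p<0.01, \*\*\*p<0.001; Gaussian-likelihood AIC; RMSE from
  in-sample residuals.
- **GWR:** one weighted least-squares fit per tract with the adaptive
  bisquare kernel `w = (1 − (d/d_max)²)²` for d < d_max, where d_max is the
  distance to the bandwidth-th nearest neighbor; an optional uniform kernel
  exists for limit checks (uniform weights at full bandwidth reproduce OLS
  exactly). Effective parameters are tr(S) of the hat matrix; the corrected
  AIC is `2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S)` with
  σ̂² = RSS/n, and the reported AIC is −2·loglik + 2(tr S + 1). The
  bandwidth is adaptive (a neighbor count, appropriate when tract areas
  vary) and selected by golden-section search over [p+2, n] on integers
  with memoized scores; a coarse 12-point grid augments the search as a
  guard against non-unimodal criteria, and near-interpolating bandwidths
  (tr S ≈ n or RSS ≈ 0) score +inf. Singular local systems fall back to a
  1e−8 ridge, then to a pseudoinverse.
- **RF** (scikit-learn): seeded bootstrap forest, 200 trees by default,
  impurity importances normalized to sum to 1, out-of-bag R² reported as a
  diagnostic.
- **GRF:** a global forest plus one local forest per tract trained on its
  `n_local_neighbors` (default 100, floor 20) nearest tracts; predictions
  blend `blend_weight · global + (1 − blend_weight) · local` (default 0.5);
  unseen locations use the local model of the nearest training tract. Local
  forests are smaller (30 trees) than the global one; for cross-validation
  only the local models actually needed for out-of-fold prediction are
  trained, which changes nothing numerically. Per-tract local importances
  are retained. Blending and neighbor counts are configurable because the
  method's sources leave them open.
- **DNN:** a feed-forward regressor (scikit-learn MLP) with a fixed, small
  architecture grid — {1, 2} hidden layers × {16, 32, 64} widths — selected
  by internal validation score, early stopping (10% validation split),
  seeded initialization, and an internally z-scored target. Training is
  refused below 100 observations: with so few records the validation split
  cannot support architecture selection, which is exactly the failure mode
  a 77-tract city exhibits. The floor is a documented constant, and the
  failure is recorded in comparison reports as an annotated cell rather
  than an abort.

## The comparison experiment

Baseline = the post-cascade demographic set; test = baseline plus the three
visit frequencies. Reporting follows the convention that statistical models
(OLS, GWR) show in-sample R², adjusted R², RMSE and AIC, while
machine-learning models (RF, DNN, GRF) show R² and RMSE from pooled tenfold
cross-validation (out-of-fold predictions pooled before computing the
metrics — stabler than averaging per-fold R² for small cities; the
per-fold alternative is a one-line change). Improvement flags compare
metrics rounded to three decimals and report exact ties as ties. RF
importances are additionally averaged over the ten training folds and
ranked.

Stepwise regression starts from the three derived measures, adds the
candidate with the smallest entry p-value below 0.05, then drops any
current variable (start variables included) whose p-value exceeds 0.05,
recording which addition triggered the drop. p-value thresholds are the
most common convention and both are exposed; an iteration cap guards
against add/drop cycles. The trace replays exactly: applying its actions in
order reproduces the final variable set.

## Numerical and reproducibility choices

- Every stochastic stage takes its own substream of the master seed; the
  pipeline embeds the config hash and seed in every JSON artifact, writes
  JSON with sorted keys, and writes CSV floats with `%.17g` (and reads them
  with round-trip parsing), so a rerun with the same config is
  byte-identical and a partial rerun can resume from intermediates.
- Degenerate inputs fail loudly with named errors: constant fields for
  Moran's I, zero-variance columns in standardization, rank-deficient
  global designs, under-determined VIF systems, empty post-filter tables.
- Problem sizes in tests and the acceptance script follow the study
  defaults (900 tracts) or the smallest sizes at which each property is
  statistically stable (e.g. 2,000 observations for coefficient recovery,
  400 for the GWR surface, 800 for the GRF split signal).

## Known limitations

- GWR and GRF assume planar coordinates; geographic CRS handling is out of
  scope.
- The negative-binomial/gravity visit process is a modeling stand-in, not
  an inference about any provider's internals; conclusions about the
  censoring-imputation step are robust across α ∈ [1.5, 2.5] but the
  marginal count distribution of real panels is unknown.
- Published city-level indices (e.g. Moran's I of 0.740/0.741/0.668)
  depend on an unstated weights specification and proprietary data and are
  not reproducible here; the package documents them as such and asserts
  nothing about them.
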
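# neighvisit

Neighborhood-level diet and physical-activity measures from privacy-censored
POI-visit panels, and how much they improve census-tract obesity estimation.

## The problem

Aggregated mobile-phone location panels record, for each point of interest
(POI) — here fast-food restaurants, fitness and sports centers, and nature
parks — how many visitors came from each census tract. Two privacy rules
distort the panel: a tract→POI count of 2–4 is recorded as 4, and a count of
1 is deleted. `neighvisit` reverses the panel from the POI side to the tract
side, undoes the censoring stochastically, and computes, for tract *j* and
each POI category,

```
visit_frequency_j = Σ_i V_ij / S_j
```

where `V_ij` is the visitor count from tract *j* to POI *i* of that category
(POIs are counted wherever they sit, inside or outside any boundary) and
`S_j` is the tract's resident device count. Censored 4s are replaced by a
draw from {2, 3, 4} with probability ∝ k^(−α) (α = 2 by default), a
power law consistent with heavy-tailed human travel behavior.

The package then asks the study's central question: do these three derived
measures improve tract-level obesity-prevalence estimation beyond standard
socioeconomic and demographic covariates? Five estimators are compared on a
*baseline* variable set (24 demographic covariates reduced by an iterative
VIF-elimination cascade at the conventional cut-off of 5) and a *test* set
(baseline + the three visit frequencies):

- **OLS** — global linear model, with adjusted R² and AIC;
- **GWR** — geographically weighted regression, adaptive bisquare kernel,
  bandwidth chosen by golden-section search of the corrected AIC;
- **RF** — random forest, with impurity importances normalized to sum to 1;
- **DNN** — a small feed-forward network (refuses to train below 100 tracts);
- **GRF** — geographical random forests: a global forest blended with one
  local forest per tract trained on its nearest neighbors.

Statistical models report in-sample fit; machine-learning models report
pooled tenfold cross-validation. Supporting diagnostics include global
Moran's I of the outcome (permutation test on row-standardized k-NN
weights), Pearson/Spearman correlations of each measure with the outcome,
and a forward–backward stepwise regression that starts from the three
measures alone and watches which survive as demographic covariates enter.

Because the real inputs (commercial mobility panels, CDC tract outcomes,
census tables) are proprietary, the package ships a first-class synthetic
generator with known ground truth: compositional and collinear
demographics, a gravity-model visit process coupled to a latent behavior
propensity that also enters the outcome, SafeGraph-style censoring, and a
simultaneous-autoregressive outcome error that produces the positive
spatial autocorrelation seen in real obesity surfaces.

## Worked example

```
python analysis/01_simulate_study.py  --seed 1 --out results/study
python analysis/02_derive_measures.py --seed 1 --out results/study
python analysis/03_diagnostics.py     --seed 1 --out results/study
python analysis/04_compare_models.py  --seed 1 --out results/study
python analysis/05_stepwise.py        --seed 1 --out results/study
```

The diagnostics stage prints (seed 1):

```
64 of 900 tracts (7.1%) excluded (under 50 residents or missing prevalence)
global Moran's I of obesity prevalence: 0.510 (E[I]=-0.0012, permutation p=0.0010)
VIF cascade: 9 rounds, removed ['pct_age_18_29', 'pct_asian',
  'pct_highschool_no_university', 'pct_white', 'pct_below_poverty',
  'pct_university', 'pct_food_stamp', 'pct_less_highschool', 'median_income'],
  15 variables retained (max final VIF 4.07)
  fast_food_vf     Pearson r=+0.460  Spearman rho=+0.494
  fitness_vf       Pearson r=-0.506  Spearman rho=-0.571
  nature_park_vf   Pearson r=-0.413  Spearman rho=-0.484
```

Obesity prevalence is strongly spatially clustered (Moran's I = 0.51,
p = 0.001); the compositional education and race shares are eliminated by
the VIF cascade; fast-food visit frequency correlates positively with
obesity prevalence while fitness-center and nature-park frequencies
correlate negatively — the signature pattern the measures are meant to
carry. The model comparison then shows the test set beating the baseline
for every model (e.g. OLS R² 0.710 → 0.796, AIC 5421.5 → 5131.0), and the
stepwise run reports that the three measures alone already reach R² = 0.515
before any demographic variable enters.

The same pipeline runs as one command (`neighvisit run-all --seed 1 --out
results/study`), is resumable from its on-disk intermediates, and is
byte-reproducible for a fixed seed.

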
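# fisherhab

Behavior-stratified habitat-selection analysis for GPS-collared forest
mesocarnivores — built around the question of how a forest-structure
specialist such as the fisher (*Pekania pennanti*) uses a managed landscape
differently when **resting** than when **moving/foraging**.  The package is
aimed at movement ecologists and quantitative wildlife biologists who want a
tested, scriptable version of the full analysis chain:

* **Track preprocessing** — accelerometer/interval behavior classification
  (resting below 6,400 activity counts; 20-min movement fixes vs. 120 ± 5 min
  resting fixes), greedy thinning to a uniform 20-min interval, 100% minimum
  convex polygon home ranges buffered by 5 km, availability sampled 1:20 from
  one shared pool per animal, and a fix-success habitat-bias screen.
* **Landscape covariates** — multi-scale circular neighborhood means
  (100/400/4000 m), topographic position index, slope and heat-load
  linearized aspect, and a forest-opening patch layer (canopy quartile
  classes ≤25/26–50/51–75/>75 %, two-pass 3×3 focal mode, strict 0.4-ha
  minimum mapping unit) with patch category, size, distance-to-edge and edge
  density (km/km²).
* **Resource selection functions** — use–availability designs fitted as
  binomial GLMMs with a per-individual random intercept,
  `logit P(y=1) = α + β′x + u_j`, `u_j ~ N(0, σ²)`, estimated by a Laplace
  approximation (cross-checked against `lme4::glmer` in the tests);
  univariate scale selection, a strict |r| > 0.6 collinearity screen,
  hypothesis-model competition by `AICc = −2LL + 2K + 2K(K+1)/(n−K−1)` with
  Akaike weights, and movement-state interaction models (dense canopy as the
  reference category, including three-way state × category × patch-metric
  interactions).
* **Functional responses** — per-individual mean use vs. mean availability,
  OLS of log mean use on log mean availability across individuals with 90%
  t-intervals, classified as *proportional* (slope CI ∋ 1 and intercept
  CI ∋ 0, the generalist signature), *decreasing* (slope CI < 1, the
  specialist signature), *increasing*, or *indeterminate*.
* **Synthetic data with known truth** — Gaussian-random-field landscapes and
  two-state (moving/resting) movement simulation with an exponential
  selection kernel `w(x) = exp(β′x)`, behavior-linked fix schedules and
  activity counts, and populations placed along between-individual
  availability gradients, so every stage above is testable against known
  parameters.

## Worked example

An end-to-end synthetic run: 8 animals tracked 4 days on a 3×3 km landscape,
moving-state selection for mesic conifer forest (β = 0.9) plus canopy (0.3),
resting-state selection for canopy (4.0) and drainages (TPI −0.46).

```python
from pathlib import Path
from fisherhab import pipeline as pl

cfg = pl.RunConfig(
    seed=1, extent=(3000.0, 3000.0), autocorrelation_range=200.0,
    n_individuals=8, duration_days=4.0, territory_radius=350.0,
    buffer_distance=150.0, scales=(100.0, 400.0),
    gradient_quantiles=(0.05, 0.95),
    truth_overrides={"beta_moving": {"mesic": 0.9, "canopy": 0.3},
                     "beta_resting": {"canopy": 4.0, "tpi": -0.46},
                     "switch_moving_to_resting": 0.15,
                     "switch_resting_to_moving": 0.3},
    hypothesis_models={"species_comp": ["prop_veg1_auto"],
                       "canopy_riparian": ["canopy_auto", "tpi_auto"],
                       "abiotic": ["elevation", "slope"],
                       "null": []},
    fit_interactions=False,
    functional_response_covariates=["canopy_400"], fr_min_used=3)
run = pl.run_pipeline(cfg, Path("demo_run"))
print(pl.read_report(run / "model_selection.csv")
      [["behavior", "hypothesis", "K", "AICc", "dAICc", "w"]].round(2))
```

prints the behavior-specific model competition:

```
behavior      hypothesis  K    AICc  dAICc   w
  moving    species_comp  3 5247.97   0.00 1.0
  moving canopy_riparian  4 5390.42 142.45 0.0
  moving            null  2 5407.32 159.35 0.0
  moving         abiotic  4 5410.43 162.46 0.0
 resting canopy_riparian  4 2136.18   0.00 1.0
 resting    species_comp  3 2183.25  47.07 0.0
 resting            null  2 2199.10  62.92 0.0
 resting         abiotic  4 2202.57  66.39 0.0
```

Species composition carries all the weight for moving animals while the
canopy/riparian structure model wins for resting animals — the selection
contrast that was simulated.  The resting top-model coefficients
(standardized, Wald 95% CIs) recover a strong positive canopy effect:

```
behavior      hypothesis               term   beta    se   lo95   hi95
 resting canopy_riparian          Intercept -3.168 0.194 -3.548 -2.788
 resting canopy_riparian         canopy_100  0.765 0.086  0.597  0.933
 resting canopy_riparian            tpi_100  0.124 0.067 -0.007  0.254
 resting canopy_riparian RandomIntercept_SD  0.510   NaN  0.294  0.884
```

(The intercept only reflects the 1:20 sampling ratio.  Coefficients are
attenuated relative to the generative kernel because availability comes from
the estimated buffered home range, not the true territory — see
`docs/methods.md`.)  The functional-response report for canopy:

```
 covariate behavior  slope  slope_lo90  slope_hi90         label
canopy_400   moving   1.19        1.09        1.30 increasing_FR
canopy_400  resting   1.11        0.98        1.24  proportional
```

With only 8 animals on a small landscape the moving slope sits just above 1
(buffered-range availability compresses between-individual differences);
the validation studies in `fisherhab.experiments` run this analysis under
controlled designs where the known answer is proportional or specialist.

The same stages are available from the shell:
`fisherhab run --demo --out demo_run`, or stage by stage
(`simulate`, `preprocess`, `covariates`, `rsf`, `funcresp`, `validate`)
with a YAML config.

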
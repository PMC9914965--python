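# vegattr

Attribution of per-pixel vegetation-change trends to mobile human activity
and climate drivers.

Urbanizing regions green or brown pixel by pixel, and the interesting
question is *why*: how much of the change tracks climate (precipitation,
temperature, radiation), how much tracks static human pressure (population,
nighttime light, PM2.5), and how much tracks *mobile* human activity — the
flows of people and vehicles that conventional static indices miss.
`vegattr` implements that analysis end to end for raster vegetation-index
records (e.g. 16-day NDVI/EVI composites on an equal-area 250 m grid),
origin–destination flow records, and covariate surfaces, and ships a
synthetic-data generator with known ground truth so that every stage has a
parameter-recovery test.

## The methods at its core

**Trend detection.** Per pixel, the Theil–Sen slope

    β = median( (yⱼ − yᵢ) / (tⱼ − tᵢ) ),  j > i

over annual mean composites (Savitzky–Golay smoothed at composite level),
with significance from the Mann–Kendall statistic S = Σ_{i<j} sign(yⱼ − yᵢ),
its tie-corrected variance Var(S) = [n(n−1)(2n+5) − Σ tₖ(tₖ−1)(2tₖ+5)]/18
and the continuity-corrected Z, tested at α = 0.05.

**Mobility indices.** OD records are binned into per-cell inflow/outflow
surfaces. Flows are only observed for the recent epoch; the historical epoch
is *backcast* with a bagged regression-tree model fitted on the late epoch
(vehicle flows from GDP + road density, human travel flows from GDP +
construction-land rate) and evaluated on historical covariates. The
late-minus-early per-cell differences are the four mobility covariates
(HFlowIn/Out, TFlowIn/Out).

**Attribution.** Pixels are split into increasing (β > 0) and decreasing
(β < 0) patterns and three engines run on the same sample table:

* PLSR (NIPALS) — standardized coefficients; "weight of coefficients" =
  |coefficient| × 100;
* bagged-tree permutation importance — %IncMSE: mean increase in per-tree
  out-of-bag MSE after permuting a covariate, over its standard error
  across trees (500 trees, 4 covariates tried per split, seeded 70/30
  train/test split);
* geographical detector — q = 1 − SSW/SST over quantile strata
  (SSW = Σ N_h σ_h²), plus all pairwise cross-stratification q₁₂ values
  classified into weaken/enhance/independent interaction categories.

## Worked example

```sh
vegattr run-all --config configs/demo.yaml --seed 0 --out demo_run
```

runs the packaged 64×64-cell, 20-year synthetic scenario (trend
0.0024 yr⁻¹ plus a negative nighttime-light effect on the slope map)
through all four stages and prints:

```
completed stages: preprocessing, change_detection, mobility_indices, attribution
report: demo_run/report.json
```

Inside `demo_run/report.json` (seed 0):

* `change_detection.mean_slope` ≈ 0.0023 — the mean recovered slope in
  index units per year, close to the configured 0.0024 baseline;
* `class_fractions.sig_increase` ≈ 0.67 — two thirds of pixels show a
  significant greening trend, while the bright-light (urbanizing) corner of
  the grid browns;
* `attribution.*.{plsr,rf,gd}.ranking[0]` = `NLight` for both patterns —
  all three engines recover the configured causal factor;
* `attribution.decrease.gd.max_interaction_q` ≈ 0.77 — the strongest
  pairwise interaction among factor changes.

The same stages are available individually (`vegattr simulate`, `vegattr
trend`, `vegattr mobility`, `vegattr attribute`), all driven by the one
YAML config.

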
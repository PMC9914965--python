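# Methods

## Scope and model

`vegattr` estimates where vegetation greened or browned on a fixed
equal-area grid and attributes those changes to factor *changes* — four
mobility indices (human/vehicle inflow and outflow change) and six
climate/human surfaces (population, nighttime light, precipitation,
temperature, radiation, PM2.5). The pipeline has four stages:
preprocessing, change detection, mobility-index construction, and
driving-mechanism analysis. All layers share one `GridSpec` (projected
meters, upper-left origin, row-major storage); cell membership for point
data is half-open, `[edge, edge + cell_size)`, so boundary points are
assigned uniquely — a convention that matters for OD endpoints landing on
cell edges and is asserted in tests.

## Preprocessing

Composite-level series are smoothed per pixel with a Savitzky–Golay filter
(default window 7 composites, polynomial order 2; both config-exposed).
These defaults follow common vegetation-phenology practice: the window is
long enough to suppress single-composite cloud spikes and short enough to
preserve the seasonal curve. Missing composites are linearly interpolated
before filtering and re-masked afterwards, so nodata never leaks into
neighbouring estimates. Edges use polynomial fitting on the first/last
window rather than mirror padding: mirror padding would break the filter's
defining property of reproducing polynomials up to the fit order exactly,
which the test suite asserts for random polynomials.

Annual values are the arithmetic mean of each year's non-missing
composites. Two masks restrict the analysis: vegetated pixels (multi-year
mean index ≥ 0.2, closed lower bound — the threshold excludes bare/water
pixels, so *keeping* values at or above it is the coherent direction), and
an urban zone where summed nighttime light over the period exceeds 4000
(strictly; the aggregation rule — a sum over the period — is a package
choice, as is any interpretation of the threshold's units).

## Change detection

Theil–Sen slope: the median of all pairwise slopes, with the sample median
(mean of the two central order statistics) for even pair counts.
Mann–Kendall: S = Σ_{i<j} sign(yⱼ − yᵢ), so S > 0 means increase; the
variance is tie-corrected (annual means rarely tie, but integer-valued
test fixtures do); Z uses the continuity correction (S∓1)/√Var(S); a pixel
is significant when |Z| ≥ z₁₋α/₂ at α = 0.05. Pixels are classed as
sig_increase / increase / no_trend / decrease / sig_decrease from
(sign β, significance), with |β| < 10⁻¹² treated as no trend. Pixels with
fewer than 2 distinct time points (slope) or 4 valid points (test) return
nodata rather than raising. No prewhitening or autocorrelation correction
is applied — the plain test is the method of record here.

## Mobility indices

OD records are binned by endpoint: each record adds its count to the
outflow of its origin cell and the inflow of its destination cell;
out-of-extent endpoints are logged and dropped from that side only.
Conservation (Σ inflow = Σ outflow = Σ counts) holds for every in-extent
batch and is asserted.

Flows exist only for the late epoch, so the historical surfaces are
backcast: a bagged regression-tree ensemble (500 trees; all covariates
tried per split when ≤ 4 exist) is fitted per direction on late-epoch
flows against same-epoch covariates — GDP + road density for vehicles,
GDP + construction-land rate for human travel — and evaluated on the
early-epoch covariates, clipped at zero and flagged simulated. Fitting on
the late epoch is the only well-posed pairing, because that is the epoch
with flow observations. Out-of-bag RMSE/R² are reported as the fit
diagnostics. Change indices are per-cell differences (late − early), used
as attribution covariates, with aggregate Σlate/Σearly ratios reported
separately.

A structural caveat: when record counts follow a link λ(origin, dest),
each cell's total contains a term proportional to the *epoch mean* of its
partner cells, which a per-cell covariate model attributes to the
intercept. Backcasting therefore carries a bias that grows with the
between-epoch covariate growth. The synthetic defaults keep epoch growth
of the flow covariates modest, which is the regime in which regression
backcasting is well-posed and which the recovery suite exercises
(historical totals within 15%).

## Attribution

The sample table holds one row per kept pixel with finite nonzero slope
and complete covariates; rows split into increase (β > 0) and decrease
(β < 0) patterns, each with a seeded 70/30 train/test partition.

* **PLSR** (NIPALS, single response): covariates and response are
  standardized; components are extracted sequentially (w ∝ Xᵀy, t = Xw,
  deflation of X and y), and coefficients are assembled as
  B = W(PᵀW)⁻¹q on the standardized scale. With as many components as the
  rank of X the fit equals ordinary least squares (asserted to 10⁻⁸).
  Default 2 components, config-exposed. The reported "weight of
  coefficients" is |B| × 100; the raw weights W are also retained on the
  model object since the two are distinct quantities.
* **Permutation importance** (%IncMSE): own bagging over decision trees so
  the statistic is computed exactly as the classical convention defines
  it — per tree, out-of-bag MSE after permuting one covariate minus the
  baseline OOB MSE; the importance is the across-tree mean over its
  standard error. Under this scaling a null covariate fluctuates within a
  few units of zero while a strong driver reaches the hundreds. Defaults:
  500 trees, 4 covariates per split, clipped with a warning when fewer
  exist.
* **Geographical detector**: factors are discretized into L = 5 quantile
  strata by default (quantiles keep strata balanced for the skewed flow
  covariates; equal-interval binning is available). Duplicate quantile
  edges collapse, empty strata drop, and strata smaller than 2 samples
  merge into the adjacent stratum so every σ_h² is defined. q = 1 − SSW/SST
  with population variances, so SSW = Σ N_h σ_h² is a literal
  within-stratum sum of squares; SST = 0 yields q = 0 by convention; q is
  clipped to [0, 1] against floating-point underflow. Pairwise interaction
  q₁₂ uses the cross-stratification (nonempty pairs only) and is
  classified: q₁₂ < min → nonlinear weaken; min ≤ q₁₂ < max → univariate
  weaken; max ≤ q₁₂ < q₁+q₂ → bivariate enhance (the q₁₂ = max tie
  resolves here); q₁₂ = q₁+q₂ within 10⁻⁹ → independent; above → nonlinear
  enhance. Significance testing of individual q values (the noncentral-F
  test) is out of scope; only magnitudes and interaction categories are
  reported.

## Synthetic generator

The generator emulates the *structure* of the study data, not any real
geography: a 64×64-cell, 250 m grid, 20 years × 23 composites of a
vegetation index with base level 0.45, baseline trend 0.0024 yr⁻¹,
seasonal amplitude 0.08, Gaussian noise σ = 0.02, and 5% cloud-like
dropout composites losing a uniform 30–70% of their value (downward
spikes, the artifact the S–G filter exists to suppress). Covariate
surfaces are Gaussian-filtered white noise (length scale 6 cells, capped
at a quarter of the grid and clipped at ±4 sd so exponential level
transforms stay finite) with fixed per-factor level scales and epoch
growth. The vegetation slope map can be tied to designated causal factors
(default: a negative linear nighttime-light effect of 0.004 yr⁻¹ per sd,
plus residual slope noise of 0.001), and the truth manifest records
exactly those factors — the recovery target for all three engines.

Flow records use a balanced endpoint design (every cell appears equally
often as origin and destination, pairing randomized) with Poisson counts
whose mean follows a monotone link of the two cells' covariates (default:
linear in the scaled covariate intensities, scale 6, 262144 records). The
balance ensures per-cell totals reflect the link rather than
endpoint-sampling noise.

What the generator does *not* emulate: real land-cover mosaics, spatial
autocorrelation of the vegetation noise, MODIS-specific error structure
(the dropout model is a stand-in, not a claim about MODIS), network
structure in the flows, or the magnitudes of real flow volumes. Passing
recovery tests therefore demonstrates correctness of the estimators and
the plumbing under known truth — not performance on real satellite or
signaling data.

## Numerical and design choices

* Continuous covariates resample bilinearly (center-based, edge-clamped,
  never outside the input min/max); counts and masks use nearest — no
  fractional counts are invented.
* Determinism: every random draw descends from the scenario seed through
  named substreams; a config + seed reproduces the full report
  bit-for-bit, asserted via a report hash.
* Problem sizes in the shipped tests and the acceptance script (64×64
  pixels, 1000-pixel recovery grids, 10–20 importance replicates at
  n = 5000) are chosen to exercise every code path at desk scale while the
  statistics remain well-resolved.
* Zero-variance covariates are dropped from PLSR with a warning; a
  constant covariate yields a single flagged stratum (q = 0) in the
  detector; an empty vegetation-change pattern raises with advice to
  adjust the scenario rather than silently producing empty engines.

## Known limitations

* The trend classes use a hard α = 0.05 cut with no multiple-testing
  control across pixels, as is conventional for per-pixel trend maps.
* Backcasting inherits the partner-mean bias discussed above; under
  aggressive epoch growth the historical totals drift high even with a
  perfectly fitted model.
* The geographical detector's q depends on the discretization; L and the
  binning method are config knobs, and results should be read with that
  sensitivity in mind.
* PLSR component count is fixed (default 2), not cross-validated.
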
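# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `alpinecast`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Bioclimatic variables

Four variables summarize a cell's monthly climatology:

* **Warmth index (WI, °C·month)** — annual sum of positive monthly-mean
  excesses over +5 °C; the classical heat-sum measure of growing conditions,
  with alpine vegetation confined below a heat ceiling (the generator's
  default places it at WI = 15).
* **TMC (°C)** — monthly mean daily minimum of the coldest month.
* **PRS (mm)** — May–September precipitation (calendar months 5–9 inclusive).
* **MSW (mm w.e.)** — maximum of a daily degree-day snowpack simulation.

The snow model accumulates precipitation as snow on days below a rain/snow
threshold (default 2.0 °C), melts at `DDF × max(0, T − T_base)` with
DDF = 4.0 mm·°C⁻¹·day⁻¹ and T_base = 0 °C, and caps melt at the current pack.
These are mid-range values from standard degree-day snow hydrology, all
configurable (`SnowModelParams`). The simulation obeys exact mass balance:
cumulative snowfall − cumulative melt = final SWE.

Because the snow model needs daily forcing and the package works from monthly
climatologies, one hydrological year (1 September – 31 August, 365 days, so a
single winter pack is contiguous) of daily weather is synthesized per cell:
temperature is the exact trigonometric (12-harmonic DFT) interpolant of the
monthly means placed at month midpoints, plus seeded Gaussian day-to-day noise
(default sd 2 °C); precipitation days are drawn at a fixed wet-day frequency
(default 0.4) and each month's total is split evenly over its wet days (at
least one forced), so scaling a month's total scales daily amounts exactly.
The synthesis seed is independent of the climate values, which yields two
useful identities: an identity scenario reproduces the baseline bioclim
bit-for-bit, and a uniform warming delta is monotone (WI, TMC never decrease;
MSW never increases).

## Delta downscaling

Scenario anomalies live on their native coarse lattice: additive deltas for
monthly mean and minimum temperature, multiplicative ratios for precipitation.
They are bilinearly interpolated (cell centers as point values, linear
extrapolation beyond the outermost centers) to the climatology lattice and
applied to the baseline. Two implementation details matter numerically: the
ratio field is interpolated as (ratio − 1) and the bilinear formula uses the
incremental form `v00 + t·(v01 − v00) + …`, so identity scenarios and uniform
deltas propagate exactly, not merely to rounding error. If a scenario
supplies a single temperature delta field it is applied to both means and
minimums; interpolated minimums are clipped to stay at or below means.

## Terrain predictors

From the DEM at fine resolution: Horn 3×3 slope and downslope aspect
(degrees clockwise from north; flat cells undefined), Zevenbergen–Thorne
general curvature (convex-up positive), TWI = ln(a / tan β) with specific
catchment area from single-direction (D8) accumulation after a minimal
priority-flood pit fill and a slope floor of tan β ≥ 10⁻³, and ridgeline
distance as the Euclidean distance transform of the ridge mask. Ridges are
drainage divides: cells whose D8 accumulation on the inverted DEM exceeds a
quantile threshold (default 0.99, configurable — no canonical definition
exists, so the parameter is surfaced rather than fixed). The outer one-cell
border, where finite differences are undefined, is excluded from model
fitting; for prediction the border takes the nearest valid value so that
aggregation to territory cells stays complete.

## The additive logistic models

Both occurrence models (zone and territory) are penalized additive logistic
models built in-package: B-spline bases (cubic, quantile knots; univariate
basis size 10, bivariate tensor 5×5 = 25), second-order difference penalties,
penalized IRLS, and a single smoothing multiplier chosen on a fixed
9-point log grid by deviance-based GCV. Effective degrees of freedom are the
trace of the influence matrix and AIC = deviance + 2·edf, the standard form
for penalized smooths; this AIC drives the all-subsets Akaike-weight variable
importance (IOV), in which the bivariate combination smooth always enters as
a single unit.

Two guards make predictions trustworthy away from the training data, where
climate-change projection necessarily operates:

* **Clamped extrapolation.** Each smooth evaluates its inputs clipped to the
  training range; beyond it the fitted effect is held constant rather than
  extrapolated polynomially.
* **Shrinkage ridge.** The difference penalty leaves linear directions
  unpenalized; under (near-)separable training data — common for sharp
  climatic limits — those directions diverge and produce arbitrarily large
  effects off the training manifold. A small fixed ridge (10⁻³ of the
  per-block data scale, not subject to the GCV search) bounds them, the same
  idea as shrinkage smooths in standard GAM software. An R/mgcv fit of the
  same data is used as an independent oracle in the test suite.

The territory model adds `log(n_surveys)` to the linear predictor as a fixed
offset, so a cell surveyed twice is expected to yield a detection roughly
twice as often on the odds scale; predictions are standardized at a reference
effort of one survey (offset 0), making maps comparable across cells.
Binary habitat uses the threshold-at-sensitivity rule: the largest threshold
retaining at least 95% (configurable) of training presences, ties resolved
upward. Bootstrap validation (default 100 replicates) resamples rows and
scores them with the single fitted model; the model is deliberately not
refitted, which is optimistic and reported as such.

## Random-forest fraction models

One `RandomForestRegressor` per community (default 500 trees, p/3 features
per split, out-of-bag R² recorded, seeded). Predictions are clipped to [0,1];
cells whose three fractions sum above 1 are rescaled proportionally (never by
truncating one community first, which would be order-dependent). Importance
is increased MSE — mean rise in prediction MSE when one predictor column is
permuted (default 3–5 permutations, seeded) — rather than any impurity-based
score. Validation is the Spearman rank correlation between predicted and
actual fractions.

## The synthetic study system

The generator emulates the *structure* of a real alpine survey region, not
any particular mountain range. Defaults define the study conditions:

* **Geometry.** A 12 km × 18 km domain with a 100-m terrain lattice (21,600
  cells), 1-km climate lattice (216 cells) and 300-m territory lattice
  (2,400 cells). This is the same nested design as a 20 km × 30 km study
  region with 60,000 fine cells, scaled to keep the full cascade and its
  24-member ensemble fast on one CPU; a 300-m lattice also does not tile
  20 km evenly, whereas it tiles this domain exactly.
* **Relief.** A meandering north–south ridge spine (Gaussian cross-profile,
  σ = 0.25 of the domain width) with along-crest undulation deep enough that
  parts of the ridgeline dip below the alpine zone — as on a real massif, and
  necessary so the territory model sees near-ridge cells without vegetation —
  plus smoothed random relief; `ruggedness` scales the whole relief field and
  peak elevation defaults to 3,000 m (max ≈ 95% of peak).
* **Climate.** Sea-level monthly normals follow a cool-temperate, winter-wet
  maritime profile; cells cool with block-averaged elevation at
  6 °C/km, with N(0, 0.3 °C) cell-month noise. Precipitation increases 30%
  per km of elevation and carries 25% spatial noise — mountain precipitation
  really is this variable, and that independent variation is what lets the
  fitted zone model attribute the alpine limit to warmth rather than to the
  collinear snowpack.
* **Vegetation truth.** Zone suitability is logistic in the four bioclim
  variables, dominated by a negative warmth-index term centred at WI = 15,
  with a hard establishment gate at suitability 0.05 (so "any cover" labels
  are well defined under truncated noise). Community fractions are
  suitability-gated terrain responses — stone pine decays with ridge distance
  (scale 400 m), fellfield hugs the crest (150 m), snowbed follows TWI — 
  jointly capped at 0.95 cover, with truncated Gaussian noise (sd 0.05)
  applied on the pre-gating scale and proportional rescaling if a cell
  exceeds full cover.
* **Territories.** Per-survey occurrence is logistic in the three aggregated
  fractions and ridge distance, with intercept −6 (occurrence essentially nil
  away from alpine vegetation, as in the real system) and a strong stone-pine
  effect. A cell surveyed n times is observed present with probability
  1 − (1 − p)ⁿ — the complementary-log construction that a log-effort offset
  identifies at fit time. Survey counts default to uniform integers 1–4;
  zero-survey cells are excluded.
* **Scenario ensemble.** 24 anomaly fields on a 4×3 lattice, scenario-mean
  warming spread evenly over 2.5–6.0 °C (an end-of-century high-emission
  ensemble range) with smooth spatial variation, minimum-temperature deltas
  tracking the mean deltas, and precipitation ratios in 0.9–1.25; every field
  value stays inside its stated range.

What passing tests on this system do show: the full pipeline recovers planted
response shapes and signs, discriminates presences near-perfectly at strong
signal, ranks planted dominant predictors first, collapses habitat under the
planted monotone-declining truth, and is bit-reproducible under a seed. What
they do not show: performance under spatial autocorrelation of residuals,
imperfect detection beyond the effort model, vegetation classification error
structure, or real topographic/climatic complexity — all absent from the
generator by design.

## Numerical choices and degenerate inputs

Probabilities are clipped via a ±35 bound on the linear predictor; IRLS runs
at most 60 iterations to a 10⁻⁹ relative deviance tolerance with a 10⁻¹⁰
jitter on the normal equations. Threshold ties resolve to the largest
qualifying value (most conservative habitat extent). The ensemble median with
an even scenario count is the mean of the two central order statistics.
Single-class training data raise a degenerate-data error rather than fitting;
the zone model requires at least 50 training cells; zero-survey territory
rows are rejected by the data container. Grids persist as ESRI ASCII with
eight significant digits; fraction invariants tolerate 10⁻⁶ for round-trips.

## Design choices where the design was open

* Zone presence/absence is delimited over the whole domain (no elevation
  cutoff), with a cell labelled present when its mean total community cover
  exceeds 0 ("any cover"); both the threshold and an elevation mask are
  configurable.
* The zone model is fitted at climate resolution (one row per 1-km cell);
  fitting at fine resolution with replicated climate values is supported but
  not the default, since replication only reweights the likelihood.
* Zone probabilities are resampled to the fine lattice by nearest neighbour,
  preserving the coarse model's values exactly.
* "Sustained" habitat for the agreement map means habitat under the current
  model *and* under the scenario's future projection; thresholds are frozen
  at their training values for all future maps.
* The fitted models are treated as in-memory objects with a pickle + JSON
  sidecar for stage re-runs; no custom binary container format is defined.

## Limitations

The GAM engine selects one global smoothing multiplier rather than per-term
penalties, and its bivariate smooth is a tensor product of B-splines rather
than a true thin-plate basis; mgcv agreement is verified on test data but the
two will not match coefficient-for-coefficient. Bootstrap validation without
refitting overstates out-of-sample AUC. D8 routing is single-direction; no
multiple-flow-direction option exists. The ensemble treats scenarios as
exchangeable and reports no within-scenario parametric uncertainty.
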
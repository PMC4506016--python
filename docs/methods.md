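# Methods

This note records the statistical model, the synthetic study system, the
numerical choices, and the design decisions behind `coastsdm`, in the spirit
of the model documentation that simulation and modelling packages ship with
their code. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The modelling frame

The unit of analysis is the cell–season–year stratum on a regular planar
grid (default 1 km cells). Cells are half-open boxes
`[x, x+1) × [y, y+1)`; a record on a shared edge belongs to the
higher-index cell. Seasons follow the local sea-weather convention —
summer Jan–Mar, autumn Apr–Jun, winter Jul–Sep, spring Oct–Dec — and one
row exists per surveyed cell, season and year. Each row carries three
responses (presence/absence; number of sightings; summed group size), the
survey effort in km, and the ten predictor values. Strata with less than
1 km of effort are removed (the threshold is inclusive: exactly 1 km is
kept), guarding against small-sample noise in barely surveyed cells.

## Candidate models

* **Presence** — binomial GLM/GAM, logit link.
* **Sightings, summed group size** — negative binomial (NB2) GLM/GAM, log
  link, `log(effort_km)` offset, so expected counts scale with effort. The
  offset applies to both count responses. A null-Poisson Pearson χ²/df
  ratio (`check_overdispersion`) above ~1.5 motivates the NB family.
* θ (the NB dispersion; variance = μ + μ²/θ) is estimated per model by
  profiling the GLM likelihood over log(α), α = 1/θ, with a bounded scalar
  search on [e⁻⁸, e⁸] (absolute tolerance 10⁻³ on log α). θ counts as one
  estimated parameter in AIC = −2 logL + 2k.
* **"GAM" terms** are natural cubic splines with exactly 3 degrees of
  freedom per predictor: 4 quantile knots (0, ⅓, ⅔, 1) of the training
  column, giving a fixed, unpenalized basis (x plus two curvature columns,
  linear beyond the boundary knots). A fixed-df basis makes the 3-df cap
  exact, makes every fit a GLM on an expanded design (reproducible, no
  smoothing-parameter search), and keeps GLM ⊂ GAM nested. A column with
  fewer than 3 distinct values degrades to a linear term.
* Predictors are z-scored with the *sample* SD; the training means/SDs are
  stored and reapplied to test and prediction frames.
* Non-convergence and (quasi-)separation (any |logit coefficient| > 30) are
  flagged, and the candidate is dropped from the ranked set with a log
  entry, rather than aborting the all-subsets run.

## Screening, multimodel inference, ensemble

Collinear pairs (Spearman |r_s| ≥ 0.7, inclusive, on the standardized
training frame) are processed in descending |r_s|; for each pair still
alive, two univariate GLMs (family matching the response, offset for
counts) decide by lower AIC which member survives; exact AIC ties fall to
the alphabetically first name; once a variable is removed its remaining
pairs are skipped. Screening is run per response, and the decision report
(pair, r_s, both AICs, outcome) is retained.

All 2^k predictor subsets (k ≤ 15 guard) are fitted per form. Akaike
weights use the numerically stable Δ = AIC − min AIC form. The 95%
confidence set is the minimal weight-ranked prefix with cumulative weight
> 0.95 (an epsilon of 10⁻⁹ absorbs float accumulation at the boundary).
Model-averaged predictions are computed on the **response scale** with
weights renormalized within the confidence set; this is what the maps
need, and avoids the full-vs-conditional ambiguity of coefficient
averaging. Full-average coefficients (absent terms = 0, GLM sets only) are
available as a secondary report. GLM and GAM sets are ranked and averaged
separately, then combined by the C-index-weighted consensus
WA_i = Σ_j C_j m_ji / Σ_j C_j, with each family's weight its mean
*training* C-index (a global mean, not per-season). The consensus is
always taken over the 95% sets; when the top model's weight exceeds 0.9
the average is dominated by it anyway.

## Evaluation and model checking

The temporal split trains on the first three survey years and tests on the
last (a 70/30 split at the default schedule). The C-index is Harrell's
concordance over all pairs with unequal outcomes (ties in predictions
count ½); it equals the trapezoidal AUC for binary outcomes and extends
unchanged to counts. It is computed within each season–year stratum
(strata with constant outcomes are skipped) and summarized as mean and
sample SD across strata.

Spatial diagnostics use the deviance residuals of the lowest-AIC model,
averaged per cell. Weights are binary distance bands, default 0–2 km
(the eight neighbours of a 1 km cell), symmetric, zero diagonal. The
correlogram reports Moran's I per distance class with a randomization
test; the two-sided p-value is (1 + #{|I_perm − Ē| ≥ |I_obs − Ē|})/(1+R)
where Ē is the mean of the permuted statistics. Centering matters: Moran's
I has null expectation −1/(n−1), and an uncentered absolute-value test is
measurably conservative. Classes with no pairs are reported as undefined,
not fatal. p-values are never below 1/(R+1).

## The synthetic study system

The generator emulates a four-year coastal survey on a 14×14 km grid
(196 cells, matching the ~194 surveyed cells of the motivating system) with
14 season–years: four seasons in 2006, 2007 and 2009, two (winter, spring)
in 2008 — the half-sampled year. Defaults, chosen once for realism:

* **Effort.** Each season–year surveys a random subset of cells targeting
  69% coverage (between-season SD 15%); surveyed cells draw
  gamma-distributed track lengths (mean 7.2 km, shape 1.5), so ~7% of
  surveyed cells fall under the 1 km filter and the filter stage is
  genuinely exercised. The mean per-cell effort reproduces the scale of the
  printed survey summary (~13 500 km over 14 season-years and ~1900
  strata). A `constant_effort_km` override supports degenerate tests.
* **Environment.** Ten predictors in their printed units and ranges: depth
  BAT (0.12–102.12 m), slope GRAD (3.48–100%), CHL (0.22–1.39 mg m⁻³),
  CHLT (6.82–88.59%), SST (25.43–29.95 °C), SSTT (5.71–15.74%), and four
  distances (km) to coast, reef, 100 m isobath and oceanographic front.
  Noise layers are Gaussian-smoothed white noise (σ = 2 cells) min–max
  rescaled into the printed ranges; distance layers are exact Euclidean
  distances to feature geometries (so brute-force distance oracles apply)
  and are therefore bounded below by 0 but not forced into the printed
  ranges. The coastline runs along the northern edge and the isobath and
  seasonal front lie east of the domain, so the predictor set is not
  internally confounded; BAT mixes a coast-distance gradient (weight 0.55,
  with the noise residualized against the gradient) with smoothed noise.
  GRAD is a noisy per-cell monotone copy of BAT (mixing 0.92) and CHL of
  CHLT, reproducing the two strongly collinear pairs of the real predictor
  set that the screening stage must resolve. SST carries a seasonal cosine
  cycle (amplitude 1 °C); the front polyline is redrawn each season–year.
* **Truth.** Coefficients act on z-standardized predictors. Occurrence:
  intercept −1.6, BAT −0.5, REEF −0.5, BATH100 −0.8, FRONT −0.6, SST −0.2
  (shallow cells near reefs, the shelf break and fronts are favourable —
  prevalence ≈ 0.2). Sightings: intercept −4.0 with the same sign pattern
  plus CHLT +0.3 (marginal mean ≈ 0.3 per stratum, θ = 1). Group size per
  sighting: log-mean 3.0 with weak REEF/FRONT/SST effects and θ = 0.2,
  giving the heavy right tail characteristic of dolphin group sizes.
* **Coupling.** Presence is drawn exactly Bernoulli(logistic(η_occ)).
  Conditional on presence, the sighting count is zero-truncated NB whose
  conditional mean is μ/p (μ = effort·exp(η_sgt)), so the marginal count
  mean is exactly μ: the logistic occurrence law, the effort-proportional
  count mean, and the presence ⇔ (count ≥ 1) consistency of the gridded
  table all hold simultaneously. Where μ/p < 1 no zero-truncated mean
  match exists (a ZTNB mean is ≥ 1) and the count degrades to 1, a slight
  upward bias confined to near-empty strata. Zero-truncated draws use
  inverse-CDF sampling; the underlying NB mean solves the truncated-mean
  equation by bracketed root finding (Brent, xtol 10⁻¹⁰).
* **Randomness.** One master seed; child streams per stage (environment,
  effort, observations) spawned via `SeedSequence`, so every artefact is
  bit-reproducible from (scenario, seed).
* **Protected area.** The default MPA polygon is a 6 × 6.5 km north-east
  block (~39 cells, the park + reserve area of the motivating system),
  sitting where the truth concentrates suitability.

What the generator does *not* emulate: real satellite-derived CHL/SST
fields (spatial spectra, cloud gaps), tidal/diurnal structure, animal
movement and hence serially correlated sightings, observer-side detection
failure, and track-level effort geometry (effort arrives per cell).
Passing tests therefore demonstrate the correctness and calibration of the
inference chain under a known generative model of the same shape as the
study system — not the ecological conclusions of any real survey.

## Problem sizes used by the checks

The test suite and acceptance script size their simulations as follows:
parameter recovery uses 100 replicates of a 45×45 single-season survey
(~2000 strata, θ = 1) and checks that estimates fall within 3 SE of truth
at least 95% of the time; ensemble discrimination uses 50 replicates at
the default study scale (196 cells, 14 season–years, candidate set
BAT/REEF/BATH100/FRONT) and requires a held-out-year ensemble C-index
above 0.7 in ≥ 90% of them; structural invariants run on 1000 randomized
instances; the correlogram's type-I error is measured on 200 iid fields
(12×12 grid, four distance classes, 199 permutations) against a
0.05 ± 0.02 band; the full acceptance run fits the complete all-subsets
chain (10 predictors screened to 8, 2 × 256 candidates per response,
three responses) in a few minutes on one CPU.

## Known limitations

* The abundance surface multiplies the expected number of sightings by the
  expected *summed* group size, as the workflow defines it; since the
  group-size response is itself a per-cell sum, the product overstates
  individuals where several sightings co-occur. The per-sighting
  alternative (sightings × mean group size) can be formed from the same
  surfaces; the default follows the workflow as stated, and totals should
  be read comparatively (inside vs outside, year vs year), not as absolute
  population sizes.
* Habitat thresholds are grid-wide *means* of the mean and SD maps; with
  strongly skewed surfaces the occasional class can be large. Cells with a
  high mean and high SD are classified occasional (the SD rule takes
  precedence); ties at a threshold fall to the low side.
* AIC (not AICc) ranks candidates, matching the workflow; at ~1300
  training strata and ≤ 25 parameters the difference is small.
* The NB profile likelihood assumes the mean structure is correct; under
  the hurdle generator the marginal count distribution is not exactly NB,
  so θ estimates are approximations even though mean coefficients remain
  consistent.
* Welch's unequal-variance two-sided t test is used for inside/outside
  comparisons; with skewed abundance surfaces its p-values are
  approximate. The t statistic is reported as outside − inside, so higher
  values inside give negative t.
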
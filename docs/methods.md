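# Methods

## Exposure definition

A county's extreme-temperature thresholds are empirical percentiles of
its pooled baseline-period daily mean temperatures — by default the
97.5th percentile for heat and the 2.5th for cold, with a (99, 1)
sensitivity pair. Percentiles use linear interpolation between order
statistics; the estimator convention matters in the last decimals of a
threshold, so it is fixed here explicitly. A day is counted as extreme
under *strict* inequality (`T > hot`, `T < cold`); ties are uncounted,
and a single day can never be both hot and cold. Counts are aggregated
per civil calendar month, leap days included. Counties need at least
100 baseline days (configurable) or threshold computation refuses to
run.

Projection-period extreme days are counted against the *same absolute
°C cutoffs* as the current period (not re-derived percentiles) — the
natural reading of holding the exposure definition fixed while the
climate shifts.

The heat-index sensitivity uses the US National Weather Service
(Rothfusz) apparent-temperature regression, Fahrenheit-native with the
published low-humidity and high-humidity adjustment terms and the
simple-formula fallback below the 80 °F regime. Hot days in that variant
are defined on the daily *maximum* apparent temperature, with hot
thresholds recomputed on the heat-index scale from the same baseline
years and percentile; cold days remain on the daily-mean scale. A
`aggregate_centroids` hook collapses multi-centroid grid series to
county means (unweighted); raster ingestion is out of scope.

## Spatial empirical Bayes smoothing

Marshall's (1991) *local* estimator with self-inclusive rook-contiguity
neighborhoods: for county *i* with neighborhood J(i),

    m_i  = Σ_J y_j / Σ_J n_j
    s²_i = Σ_J n_j (r_j − m_i)² / Σ_J n_j
    w_i  = (s²_i − m_i/n̄_i)₊ / [ (s²_i − m_i/n̄_i)₊ + m_i/n_i ]
    smoothed_i = m_i + w_i (r_i − m_i)

with n̄ the neighborhood mean population; a negative prior-variance
estimate truncates to zero (full shrinkage to the local mean). Isolated
counties fall back to the same formula on the global (all-county)
neighborhood and are flagged. Smoothed rates always lie between the raw
rate and the local mean, and are never negative.

By default smoothing is applied *pooled*: one shrinkage factor per
county from period-total deaths and person-months, applied
multiplicatively to each monthly rate. This stabilizes reported rates
while remaining exactly absorbable by the county fixed effect, so the
exposure coefficients are essentially unchanged — which is the intended
role of smoothing here (rate stabilization, not effect modification).
A monthly-cross-section mode and an off switch are provided for
sensitivity.

## Estimation

The exposure–mortality association is estimated by Poisson
pseudo-maximum likelihood. The default outcome is the (smoothed,
age-group-specific) monthly mortality rate per 100,000 with analytic
weights equal to population; a count-with-offset mode (deaths with
`log(pop/1e5)` offset) gives the same score equations and is provided
as an alternative. The pseudo-likelihood view matters: outcomes may be
non-integers, and no Poisson variance assumption is made — inference is
based on the heteroskedasticity-robust sandwich
`A⁻¹BA⁻¹ · n/(n−k)` with `A = X̃ᵀWX̃`, `B = X̃ᵀdiag(s²)X̃`, `s = w(y−μ̂)`,
and `k` counting explicit plus absorbed parameters. A county-clustered
variant is available but off by default. Fits are by-stratum: each age
group (and any other subgroup) gets its own model, mirroring the
age-heterogeneity of the association.

County, calendar-month and year fixed effects are absorbed, not
materialized: each IRLS iteration residualizes the working response and
regressors against the three FE sets by alternating weighted
within-group demeaning (tolerance 1e-10 on the applied group means,
relative to column scale), then solves the weighted least-squares
update on the demeaned system. Convergence is declared when the
relative deviance change falls below 1e-9; fitting is fully
deterministic. FE groups whose outcome sums to zero are perfectly
predicted (their log-rate diverges); such observations are dropped
iteratively before fitting and logged. Collinear design columns are
detected on the demeaned design via pivoted QR and reported by name.

Covariates enter as restricted (natural) cubic splines in Harrell's
parameterization — `k` percentile-placed knots give `k−1` columns
including the linear term; the basis is linear beyond the terminal
knots with continuous first and second derivatives. The covariate list
and per-covariate knot counts are fully configurable (default 4 knots);
nothing is hard-coded.

Specification choice uses BIC = −2·log-pseudolikelihood + k·ln(n) with
`k` the explicit (non-absorbed) parameter count, ties broken toward
fewer parameters. One caveat is documented deliberately: with
population analytic weights the pseudo-likelihood is on the
person-month scale, which inflates likelihood differences relative to
the penalty; BIC comparisons (e.g. linear vs. spline-in-exposure) are
therefore meaningful on the count likelihood, and the tests exercise
them there.

`100·(e^β − 1)` converts a coefficient to the percent change in the
monthly rate per additional extreme day, with interval endpoints
`100·(e^{β±1.96·SE} − 1)`. Two-sided Wald p-values; no multiplicity
adjustment.

## Attribution

Excess deaths are counterfactual: predicted deaths at observed exposure
minus predicted deaths with extreme-day counts set to zero, everything
else (fixed effects, covariates) at observed values. In the log-linear
model the heat component is `Σ_ct μ̂_ct (1 − e^{−β̂_h H_ct})` (lag terms,
when present, are zeroed together with the contemporaneous term), cold
is analogous, and *combined = heat + cold* by construction — each
component zeroes one exposure at a time from the same joint fit, so the
reported components are exactly additive. Totals are divided by the
number of years for mean annual figures; per-1M rates divide by the
population at risk.

Note the additive decomposition differs from the "both exposures zeroed
at once" counterfactual `Σ μ̂(1−e^{−β̂_hH−β̂_cC})` in county-months where
H and C are both positive; with seasonal exposure the overlap is
negligible and additivity is what published component tables satisfy.

Uncertainty: the delta method on the exposure-coefficient block of the
robust covariance. Every estimate carries its analytic gradient keyed
by fit, so sums across strata (older + younger = all adults), per-capita
rescalings, and ratios (percent change, whose numerator and denominator
share β̂) propagate variance exactly, with independent strata
contributing block-diagonally. The gradient of the heat excess is
`Σ H μ̂` in β_h and `Σ C μ̂ (1−e^{−β_h H})` in β_c (μ̂ itself depends on
every exposure coefficient). A parametric-simulation alternative
(`excess_ci_simulation`: draws from N(β̂, V̂), default 10,000,
seed-controlled, percentile interval) is provided; the two agree
closely when the excess is near-linear in β over the CI's range.
Aggregates built from subgroup-restricted fits are deliberately not
constrained to sum to the national figure.

## Projection

Mid-century projection freezes the fitted model — coefficients, county
and calendar-month effects, covariate contributions — and substitutes
only exposure and population. The exposure-free linear predictor is
averaged over the (balanced) current-period years per county × calendar
month, which sets the year effect to its period mean (a last-year
option exists); projected exposure is the per-GCM 30-year-style mean
monthly count; projected population is the scenario's county total for
the stratum. Each GCM is evaluated separately and the *arithmetic mean
of per-GCM deaths* is reported, matching ensemble-averaging practice;
the CI reflects coefficient uncertainty only, evaluated at the
ensemble-mean exposure — climate-model spread is reported separately as
the per-GCM min/max, never folded into the CI. Only the declared
pairings SSP2-4.5 and SSP5-8.5 are accepted.

Percent change versus the current period is `100·(P−C)/C` with a
delta-method CI on the ratio using the shared coefficient covariance.
An identity scenario (projected exposure = observed, projected
population = current) reproduces the current-period estimates
bit-for-bit in rate mode; this is a standing regression test.

## The synthetic study

The generator emulates the statistical structure of the real data
sources rather than their content:

* **Temperatures** `T(c,d) = a_c + A_c sin(2π·doy/365.25 + φ_c) + ε`,
  with county means U(4, 18) °C, amplitudes U(8, 14) °C, peak near
  mid-July, and AR(1) noise (ρ = 0.7, stationary sd 3.5 °C) so threshold
  exceedances cluster into runs as real heat waves do. Daily maxima add
  a county-constant diurnal half-range U(4, 7) °C; relative humidity is
  a temperature-anticorrelated noisy series for the heat-index variant.
* **Pseudo-GCMs**: one projection-period weather realization, plus a
  constant per-GCM offset drawn once per model — N(2.0, 0.4) °C for the
  intermediate pathway, 1.6× those draws for the high pathway
  (correlated across pathways, as in real ensembles). Constant offsets,
  not time-varying trends: sufficient to exercise the ensemble-mean
  machinery, and a documented limitation. Under these defaults hot days
  rise by roughly 130% / 240% and cold days fall by roughly 65% / 83%
  in the two pathways — the qualitative structure of downscaled
  mid-century ensembles.
* **Deaths**: `deaths_ct ~ Poisson(pop/1e5 · exp(log r₀ + α_c + γ_m +
  δ_y + β_h H + β_c C))` per stratum, with seasonal month effects
  (winter-peaking), small county and year effects, and planted per-day
  effects at published-scale values: older adults (base rate
  330/100k/month, 22% of county adults) +0.09%/hot day, +0.26%/cold
  day; younger adults (35/100k/month, 78%) +0.17% and +0.27%. An
  expected-count overflow guard aborts absurd configurations.
  Covariates are smooth county-year series with no mortality effect, so
  fitted covariate terms should be null.
* **Scale**: 100 counties on a 10×10 grid (rook adjacency), 5 baseline
  + 5 current + 5 projection years, so the full pipeline runs in
  seconds and 50-replicate Monte-Carlo checks stay within a test
  budget. County adult populations are drawn U(200k, 3M): the toy has
  ~31× fewer counties than a ~3100-county national study, so each toy
  county carries the person-time of ~31 real ones; a design-time power
  calculation shows this gives the 0.09%-per-day effect a per-fit
  standard error near 0.03 percentage points, making a 50-replicate
  mean-bias criterion of 10% of truth resolvable rather than
  noise-dominated.
* **Populations**: constant within the current period; mid-century
  county populations scale by SSP-specific stratum factors taken from
  published mid-century medians (SSP2: older ×1.19, younger ×0.868;
  SSP5: ×1.35, ×0.985) with per-county lognormal jitter (sd 0.10).
* **Truth object**: generating parameters, per-row true log-rates, and
  closed-form expected excess `Σ μ(1−e^{−βH})` per component — the
  attribution identity is checked to 1e-10 relative.

What the synthetic study does *not* emulate: spatial correlation of
weather across counties, realistic US climatology or demographic
pyramids, covariate–mortality confounding, time-varying warming trends,
within-county exposure heterogeneity, or harvesting/displacement
dynamics. Passing tests therefore demonstrate the *statistical
machinery* — estimator correctness, CI calibration, attribution and
projection identities — not real-world effect sizes. In the synthetic
world the planted cold effects are large relative to heat, so the
combined burden can *fall* under the intermediate scenario even as heat
deaths rise; component-level results carry the interpretable signal.

## Numerical conventions

* 95% intervals use z = 1.96 throughout.
* IRLS deviance tolerance 1e-9 (relative), demeaning tolerance 1e-10,
  maximum 100 IRLS iterations (error with trace on failure).
* Mean-annual division is performed as a single division so the
  identity-scenario projection matches attribution bit-for-bit.
* CSV outputs are written at 6 significant digits with a full-precision
  parquet sidecar; the manifest records seed, config hash and library
  versions. All randomness flows from one integer seed; identical
  config + seed reproduce outputs byte-for-byte.
* Degenerate inputs fail loudly by policy: constant temperature series
  (hot = cold threshold), counties below the baseline-day floor,
  non-finite temperatures, RH outside [0, 100], non-positive
  populations, empty year ranges, unknown scenario pairings, and
  out-of-sample counties in prediction all raise typed errors naming
  the offending units.

## Known limitations

Beyond the synthetic-data caveats above: no overdispersion modelling
beyond robust SEs; no spatial correlation in errors; no distributed-lag
nonlinear structure (a single 1-month lag is the only dynamic term); no
adaptation (e.g. air-conditioning uptake) in projections; projection
CIs exclude climate-model spread by design; attribution is ecological —
no individual-level inference.
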
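# Methods

## Design and estimator

`casets` implements the case time-series design for small areas: every
zone contributes its own daily count series, and zone × year × month
strata absorb between-zone differences and slow temporal drift. The
likelihood is Poisson conditional on stratum totals, which coincides
with the profile likelihood of the model with explicit stratum
intercepts; the implementation profiles the intercepts analytically each
iteration (`a_s = log Σy_s − log Σμ*_s`) and takes IRLS steps on
within-stratum weighted-centred covariates (Frisch–Waugh absorption).
The converged coefficients and the inverse profile information are
identical to the explicit-dummy GLM to numerical precision; this
equivalence is the central test of the model module, checked against an
independent Newton solver and against `statsmodels` (test suite only —
the fitting path has no statsmodels dependency).

Overdispersion is handled quasi-likelihood style: the covariance is
scaled by the Pearson dispersion `φ̂ = χ²_Pearson / (n − p − S)` where
`S` counts used strata. Strata whose counts are all zero carry no
information in the conditional likelihood; they are dropped and counted.
Model comparison uses `QAIC = −2ℓ/φ_ref + 2(p+1)`, with `φ_ref` taken
from the richest candidate; the stratum count is constant across
candidates so its omission from `p` cancels in comparisons.

Convergence: relative log-likelihood change below 1e-9 (or 100
iterations), with step-halving on any likelihood decrease. Columns with
within-stratum variance below 1e-12 are inestimable under conditioning;
they raise an error, except in the seasonal-by-year block where they are
dropped with a warning (monthly strata can swallow parts of that
interaction, mirroring what a generic fitter would silently do).

## Bases

Natural cubic splines are built from a cubic B-spline basis restricted
to the null space of the boundary second-derivative constraints;
evaluation outside the boundary continues the boundary tangent (linear
tails). With K interior knots the basis has K+2 columns including the
constant, K+1 without it. The truncated-power construction is kept in
the test suite as an independent span oracle.

The cross-basis crosses an exposure-dimension spline (default: interior
knots at the 25/50/75th percentiles of the fitted temperatures, boundary
at their range) with a lag-dimension spline over integer lags 0–7
(default: one interior knot at lag 1, knots placed on the log(lag+1)
scale so flexibility concentrates at short delays). Columns are ordered
exposure-index-fastest, and the resolved spec (knots, boundaries,
ordering) serialises to JSON so fits, predictions and pooling can live
in separate invocations; pooling refuses estimates whose spec
fingerprints differ.

Two deliberate choices where conventions diverge:

* **Lag-dimension intercept.** The exposure spline omits the constant
  (differences against the reference remove it anyway), but the lag
  spline *keeps* it. Strata absorb constants in time, not in lag:
  without the lag constant the surface could not represent an effect
  flat across lags 0–7, biasing every cumulative summary. This matches
  the convention of the standard DLNM software.
* **Exposure knots.** Percentile placement (25/50/75) is the common
  DLNM default; equally spaced knots are available by passing explicit
  knots. Nothing in the package asserts which variant any particular
  published analysis used.

Rows lacking a full 7-day exposure history (the first week of each
zone's series) are flagged and excluded from the likelihood rather than
imputed.

## Effect summaries

The overall (lag-cumulated) contrast at temperature x versus reference
x₀ is `a(x) = (R(x) − R(x₀)) ⊗ s`, with `s_k = Σ_l C_k(l)`; then
`log RR = a·β_cb` and `se² = a·V_cb·aᵀ` (delta method, 95% CI with
z = 1.96). The reference is the median anchor by default; anchors are
computed from the day-weighted pooled temperature series of the
reporting unit (zone, region, or state — per-zone anchoring is
available). Curves are evaluated on 200 grid points between the basis
boundaries (≈0.2 °C resolution at a typical statewide range); requests
outside the boundary are refused because the spline tails are linear
extrapolations. The minimum-risk temperature is the grid argmin, ties
broken toward the lowest temperature.

Pooling is multivariate inverse-variance (fixed-effect) by default —
three regions are too few for a stable between-region covariance — with
an entrywise method-of-moments random-effects estimator available that
reduces exactly to DerSimonian–Laird in the scalar case (between matrix
eigenvalue-truncated to positive semi-definite).

## Synthetic data generator

The generator emulates the data structure the design assumes, with an
injectable known truth:

* **Temperature**: per zone, regional annual mean (defaults 13.5 / 16.3
  / 17.6 °C for a mountains / piedmont / coast split) + seasonal
  sinusoid (amplitude 10 °C, trough mid-January) + stationary AR(1)
  noise (ρ = 0.8, innovation SD 2.2 °C), giving a marginal SD near 8 °C.
  Dewpoint is temperature minus a non-negative depression draw
  (mean 4 °C, SD 2 °C), so derived RH is always in (0, 100].
* **Counts**: log-rate = log(baseline 5 visits/zone-day) + zone × year ×
  month stratum deviations (SD 0.1) + day-of-week offsets (±0.05ish,
  weekday peak) + a smooth winter-peaking seasonal term (amplitude 0.1)
  + the lag-weighted exposure effect. Overdispersion (default φ = 1.5, a
  free choice — source count data rarely document their dispersion) is
  induced by gamma-mixing with per-observation shape μ/(φ−1), which
  yields Var = φμ exactly.
* **Truth surfaces** are serialisable (null / linear / threshold /
  U-shape) with 8 non-negative lag weights summing to 1 (default: a
  front-loaded decay). `true_cumulative_rr` exposes the generative
  truth for recovery tests, and a numerical CDF inversion provides the
  theoretical marginal temperature percentiles so effects can be
  calibrated to "RR at the 97.5th percentile" targets without
  simulation.
* **Seeding**: one master seed; per-zone substreams derive from spawn
  keys, so enlarging the panel never perturbs existing zones.

Two generator details interact with the fitter and are deliberate:

* The generator pads the first week's missing lag history by repeating
  the first temperature, while the fitter drops incomplete rows; on
  multi-year series the edge effect is negligible and both behaviours
  are tested.
* The seasonal count term is the *projection* of the sinusoid onto the
  span of the df=3 day-of-year spline plus constant. A raw sinusoid is
  not exactly representable by that spline, and because its phase is
  locked to the temperature cycle the unrepresentable remainder acts as
  seasonal confounding rather than noise. Keeping the generative
  seasonality inside the model's seasonal function space makes recovery
  experiments measure estimator behaviour, not seasonal-basis
  approximation error; the note below on what the tests do not show
  applies directly.

## What the synthetic tests do and do not show

Passing recovery and coverage tests show the estimator is consistent and
its quasi-Poisson intervals are calibrated *when the model is correctly
specified up to the lag shape*: the generator has no spatially
correlated temperature fields, no population mobility, no reporting
delays, no unmeasured slow confounders beyond the strata, and its
seasonal term lies in the adjusted-for function space. Real data satisfy
none of these exactly; in particular, seasonal signal outside the
df=3-per-year space would confound the temperature effect in either
direction. The default lag weights are *not* inside the lag-spline span,
so the experiments do include lag-shape misspecification of realistic
size.

## Problem sizes and defaults used in the shipped experiments

* Oracle equivalence: 10 zones × 2 years (~7,300 rows).
* Recovery/coverage: 25 replicates of 100 zones × 4 years (~146,100
  rows each), true cumulative RR 1.05 at the 97.5th percentile; the
  coverage band for 25 replicates is [0.84, 1.00].
* Type-I: 100 null replicates of 30 zones × 3 years, band [2%, 9%] for
  CI exclusion of RR = 1.
* Subgroup minimum: strata under 1,000 visits are reported as
  insufficient rather than fitted (configurable).
* No multiple-testing correction is applied across subgroup cells;
  per-cell 95% CIs are reported as-is.

## Known limitations

* Exact conditional inference, penalised/random-effect variants, and
  autocorrelation-robust errors are out of scope.
* The `doy × year` interaction under monthly strata is partially
  collinear by construction; the drop-with-warning behaviour keeps fits
  reproducible but means the "seasonal trend" coefficients are not
  individually interpretable.
* Lag-specific (non-cumulative) surfaces and attributable fractions are
  not computed, only the lag-cumulated curve and its summaries.
* ICE quartile stratification refits on zone subsets; it does not model
  effect modification within one joint likelihood.
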
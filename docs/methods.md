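# Methods

## The design and the estimand

`aircrossover` implements a time-stratified case-crossover analysis of
short-term environmental exposure and death. Each death contributes one
*stratum*: the case day (the death date) plus its referent days — every
other day in the same calendar year and month falling on the same day of
week. A death on Wednesday 2018-05-02 is therefore compared with May 9, 16,
23 and 30, 2018. Referents constructed this way automatically match
season, long-term trend and day of week, and each case acts as its own
control, eliminating all individual-level time-invariant confounding.
Every stratum has 3 or 4 referents; enumerating all days of 2015–2019 gives
the exact average 3 + 730/1826 ≈ 3.4 controls per case.

Within a stratum the model is a conditional (matched-set) logit: the
probability that the event fell on the observed case day rather than a
referent day is

    P(case = i | stratum s) = exp(x_i'β) / Σ_{j∈s} exp(x_j'β),

and the analysis maximises the product of these over strata. Any covariate
constant within a stratum cancels. The exposure of interest enters as the
MA 0–1 moving average (event day and the previous day), pre-divided by its
reporting unit (10 µg/m³ for particulate and gaseous pollutants, 1 mg/m³
for CO) so that β is directly the log odds ratio per reporting unit.
Effects are reported as percent change in odds, (exp(β) − 1) × 100, with
Wald 95% CIs (z = 1.959964).

Adjusted models add natural cubic splines (df = 4) of the MA 0–4 moving
averages of daily mean temperature and relative humidity. The spline basis
is the truncated-power natural cubic construction (linear beyond the
boundary knots); with df = 4 there are five knots — boundary knots at the
1st/99th percentiles of the covariate over retained observation days and
interior knots at the 25th/50th/75th percentiles. The covariate is
standardised before the cubic terms are formed purely for numerical
conditioning; knots and standardisation constants are frozen in the
`SplineSpec` so fitted curves can be evaluated on new grids.

## Exposure assessment

Daily fields live on a regular lat/lon grid of cell centers. Exposure at a
residence is the bilinear weighted average of the four surrounding cell
centers. When some of the four cells are missing on a day, the remaining
weights are re-distributed to sum to one; when all four are missing the day
is missing. Points up to half a grid spacing outside the hull of centers
are clamped onto the nearest edge cell pair (equivalent to re-distributed
weights over two cells); farther points are an error. Interpolation is
done directly in degrees — at ~10 km cell size the metric distortion is
irrelevant. Missing exposure is never imputed: an observation day with a
missing required covariate is dropped; a stratum that loses its case day is
dropped whole (its conditional likelihood is undefined), and a stratum
with no remaining control is dropped as uninformative. Every removed row
is assigned to exactly one exclusion-log category.

Lag metrics: `lag k` is the interpolated value k days before the event;
`MA k0–k1` is the arithmetic mean over the window, missing if any window
day is missing or precedes the field's date axis. A utility computes daily
maximum 8-h ozone means over the 17 within-day windows (windows never cross
midnight; a window with a missing hour is skipped).

## Fitting and inference

The conditional log-likelihood, gradient and Hessian are computed
analytically with per-stratum log-sum-exp stabilisation, and maximised by
Newton–Raphson with step-halving. Convergence requires max |gradient| <
1e-8 or a relative log-likelihood change < 1e-12; coefficients diverging
past |β| > 50 raise a separation error naming the covariate, and a singular
information matrix (e.g. a covariate with no within-stratum contrast)
raises a rank-deficiency error. The covariance is the inverse observed
information at the maximum. BIC = −2ℓ̂ + k·ln(S) uses the number of strata
S as the sample size, since strata are the independent units of the
conditional likelihood. Nested models are compared by the likelihood-ratio
chi-square; the joint subgroup test compares pooled adjusted fits with and
without pollutant-by-level interaction columns (L − 1 df; the subgroup main
effect is stratum-constant and cancels, so it is never entered).

Meteorology lag selection fits one adjusted model per candidate
(lag 0, MA 0–1 … MA 0–4 applied to both temperature and humidity) on the
identical row set — comparisons across differing rows would be invalid —
and ranks by BIC (all candidates have equal parameter counts, so this is a
pure likelihood ranking). Lag-sensitivity tables use the same common-row
restriction.

Two-pollutant models (one particulate + one gaseous term plus the
meteorology splines) are fitted only for pairs passing the collinearity
screen: Pearson r of the MA 0–1 exposures over observation days must not
exceed 0.8; an undefined r (zero variance) also refuses the pair.

Concentration–response curves replace the linear pollutant term with a
df-4 natural spline of the MA 0–1 concentration. The curve is
η(c) = [B(c) − B(c_ref)]'β̂ over a grid spanning the 1st–99th percentile,
with pointwise delta-method CIs from the fitted covariance; it is exactly 0
with zero-width CI at the reference. The reference concentration is the
median over retained observation days by default and is config-exposed,
since no single convention dominates.

## The synthetic-data generator

The generator emulates the statistical structure of gridded daily
pollution/meteorology surfaces and of mortality surveillance, without
reproducing any real geography:

* **Fields.** Each variable is built from a unit-variance standardised
  anomaly — AR(1) in time with spatially smooth (Gaussian-kernel
  correlated) innovations — plus a sinusoidal seasonal cycle, then mapped
  through its marginal: log-normal for pollutants (median and geometric SD
  as parameters, guaranteeing positivity and a realistic right skew) or
  Gaussian for meteorology (Gaussian concentration-like fields must keep
  their mean at least 4 innovation SDs above zero). Cross-variable
  correlation comes from shared latent factors; the three particulate
  series load ~0.95 on a common factor, giving pairwise r ≈ 0.85–0.9 as in
  heavily coupled PM measurements, while gas–PM correlations stay moderate.
  Missingness is injected completely at random at a configurable rate.
* **Population.** Residences are uniform in the grid interior (an
  edge-testing mode places a tenth of them in the half-spacing band outside
  the hull to exercise weight re-distribution); categorical attributes are
  drawn from configurable frequencies defaulting to a realistic national
  mortality composition (57.9% men, 89.5% below high-school education,
  66.5% farmers, seven regions, five disease subtypes).
* **Deaths (stratum-first).** Each stratum samples a person, a year-month
  and a weekday; the candidate days are all such weekdays of that month —
  exactly the referent set the analysis will rebuild — and the case day is
  drawn from the multinomial with weights exp(β·x + γ_T·T + γ_RH·RH), where
  x is the causal pollutant's MA 0–1 per reporting unit *computed through
  the same bilinear linkage the analysis uses*. Because the sampling law
  is literally the conditional-logit likelihood, the fitted model is
  consistent for the injected β with no approximation, for any marginal
  exposure distribution. A concave option replaces β·x with the
  tangent-matched square-root term β·(2√(x·r) − r), producing the
  concave-down curve shape; subgroup effect modification injects
  level-specific percent shifts.

The national preset centres pollutant medians at realistic national
values (PM2.5 36.4, PM10 63.3, PM1 24.7, NO2 26.1, SO2 13.5 µg/m³, CO 0.88
mg/m³, O3 81.6 µg/m³), winter-peaking pollutant seasons, summer-peaking
ozone and temperature (mean 16.3 °C, seasonal amplitude 11 °C), humidity
mean 72.8%, and mild meteorology confounders (γ_T = 0.06 per °C,
γ_RH = 0.02 per %RH on the MA 0–4 scale). Daily persistence of pollutant
anomalies is deliberately low (AR(1) = 0.3) and geometric SDs are high
(0.49–1.10 across pollutants): the preset is defined to make per-10-unit
effects estimable at 30,000 strata. That calibration was fixed once, by an
a-priori power analysis targeting a within-stratum SD of the
per-reporting-unit MA 0–1 exposure near 3 units, which keeps the Monte
Carlo SE of a 10-replicate mean recovery below ~0.07 percentage points.
The log-normal marginal is used for pollutants (rather than a truncated
Gaussian) because the stratum-first generator keeps the truth exact under
any exposure distribution while preserving positivity at these variances.

### What the generator does *not* emulate

Real exposure series have stronger day-to-day persistence, spatially
structured (not MCAR) missingness, geocoding and retrieval error, and
within-city exposure gradients that a 10-km grid cannot resolve; real
mortality has spatial clustering and seasonality of baseline risk (which
the design absorbs) plus data-entry artifacts (which it does not). Passing
recovery tests therefore demonstrates the *correctness of the estimator and
pipeline under the design's own assumptions*, not robustness to
measurement error or residual time-varying confounding in real data.

## Experiment problem sizes

Recovery experiments use 10 replicates × 30,000 strata per pollutant on an
8×8, two-year grid preset. Calibration experiments (null CI coverage, the
interaction-LRT size, BIC lag selection, lag specificity) use a one-year
4×4-grid variant of the same preset with 250–4,000 strata and 20–500
replicates — sizes chosen so each binomial check has Monte Carlo SD well
inside its assertion band. The lag-specificity experiment injects 1.5% per
10 µg/m³ at 4,000 strata so the MA 0–1 effect is clearly detectable while
the leakage of the MA 0–1 signal into the weakly correlated lag-2/lag-3
exposures (daily AR(1) = 0.3) stays far below one standard error.

## Known limitations

* Inference is Wald/likelihood-ratio asymptotics; no exact conditional or
  permutation inference, no Firth correction for sparse strata.
* No distributed-lag nonlinear models; lags are single days or flat moving
  averages.
* The bilinear scheme assumes a regular lat/lon grid of cell centers; no
  reprojection or kriging.
* Subgroup analyses apply no multiplicity correction across levels (one
  joint interaction p per variable), matching common reporting practice;
  this is configurable only in the sense that the per-level tables carry
  their own CIs.
* The CLI stores intermediates as CSV for inspectability; very large
  studies would want a binary interchange format.
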
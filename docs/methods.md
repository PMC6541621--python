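# Methods

## Survey model and data flow

The package analyses double-observer ("double-platform") aerial
line-transect surveys. An aircraft flies systematic parallel transects at
altitude h = 152.4 m (500 ft); two observer teams — mid-seat and rear-seat —
independently record dolphin schools with inclinometer declination angles,
which convert to perpendicular distances x = h / tan(angle). The rear seats
cannot see the strip directly beneath the aircraft; the view limit of 65°
below horizontal puts the inner edge of the shared visible strip at 71 m,
which becomes the left-truncation distance. Right truncation (570 m for the
summer/autumn configuration, 660 m for winter/spring) removes outlier
detections.

Records from the two platforms are resolved into unique sightings by greedy
one-to-one matching within transect and aircraft side, closest in time
first (ties by declination difference), with defaults of 10 s and 10°.
Rationale for the defaults: at the 185 km/h survey speed a school is abeam
for only a few seconds, so genuine duplicates agree in timing to seconds.
Matched pairs average their distances and school sizes; the count identity
n_unique = n_mid + n_rear − n_matched always holds. Manual review, which
field teams use in practice, is replaced by this deterministic rule; the
tolerances are arguments, not constants.

## Detection: MRDS with point independence

**DS component.** The detection function is half-normal
g(x) = exp(−x²/2σ(z)²) or hazard-rate g(x) = 1 − exp(−(x/σ(z))^−b), b > 1,
with log-linear scale σ(z) = exp(β₀ + Σβₘzₘ) in standardized sighting
covariates (sea state, cloud cover, turbidity, glare, school size, side).
Distances are analysed continuously, re-zeroed at the left-truncation
boundary (x′ = x − 71 m) so that g(0) = 1 refers to the closest observable
distance — the same distance at which the MR component estimates p(0). The
conditional likelihood Π g(x′ᵢ)/∫₀^w g(u)du is maximised by BFGS from five
jittered starts (seeded); the half-normal strip integral uses its erf
closed form, the hazard-rate integral 61-node Gauss–Legendre quadrature.
The hazard shape is parameterized b = 1 + exp(η) to keep g monotone
decreasing. Standard errors come from the inverse observed information
(central-difference Hessian).

Model search mirrors survey practice: both keys, scale covariates added
one at a time while AIC improves; candidates are ranked by AIC, exact ties
broken by goodness of fit (largest Kolmogorov–Smirnov p, then
Cramér–von Mises p), then by estimate CV. GOF statistics are computed
against the covariate-averaged fitted CDF; because parameters are
estimated, p-values use a parametric bootstrap (default 199 refits on
samples drawn from the fitted model), with the optimistic asymptotic
p-values reported alongside for reference.

**MR component.** Each platform's conditional detection probability —
detecting a school given the other platform detected it — is a logistic
GLM in boundary-shifted distance. The intercepts give p(0) per platform,
combined under point independence as
p(0) = 1 − (1 − p(0)_mid)(1 − p(0)_rear). Independence is assumed *only*
at the boundary distance; at larger distances observer detections are
expected to correlate positively (big schools are conspicuous to both
teams), which is why the shape information comes from the pooled distance
data instead. Each sighting's inclusion probability is
p̂ᵢ = p(0) · eswᵢ / w with eswᵢ = ∫₀^w g(u; zᵢ)du.

The variance of the combined p(0) uses the delta method with the full
2×2 structure: the two conditional fits share the duplicate records, so
their cross-covariance is estimated by the stacked-score sandwich
Cov(θ₁,θ₂) = A₁⁻¹B₁₂A₂⁻¹ over the shared rows. Calibration runs showed the
independence approximation understates the SE by ~20% (88.5% of draws
within 2 SE instead of ~95%); with the cross term the rate is 93%.

## Abundance

Horvitz–Thompson per stratum: covered strip area a = 2wL, and

    N̂_schools = (A/a) Σ 1/p̂ᵢ,  N̂_animals = (A/a) Σ sᵢ/p̂ᵢ,
    D̂ = N̂_animals/A,           E[s] = N̂_animals/N̂_schools.

A stratum flown without sightings reports an all-zero row, matching real
survey output. Variance has two additive parts:

* **detection** — central-difference gradient of (N̂_schools, N̂_animals)
  with respect to every DS and MR parameter, propagated through the
  block-diagonal parameter covariance;
* **encounter rate** — between-line variability of the detection-corrected
  per-transect totals Tₖ, var = [K/(K−1)](L/K) Σ lₖ(Tₖ/lₖ − T/L)², with
  the analogous cross term supplying cov(N̂_schools, N̂_animals) for the
  mean-school-size CV by the ratio delta method. The per-line totals reuse
  the globally fitted detection model; lines are the sampling units. The
  estimator is validated against a 500-resample transect bootstrap
  (agreement within 20%, typically within a few percent).

Confidence intervals are log-normal: (N̂/C, N̂·C) with
C = exp(z√ln(1+cv²)), z₀.₉₅ = 1.959964. Strata pool by summing totals and
variances (strata are independent); pooled density is ΣN̂/ΣA and pooled
mean school size the ratio of pooled totals. Over 200 simulated surveys at
the study conditions the pooled 95% interval covers the realised true N
93% of the time.

## Habitat model

Counts of individuals (school sizes summed) are binned into 5-km segments
along transects; a trailing remainder shorter than 1 km merges into the
previous bin. Each segment carries an offset area 2w·length so the fitted
mean is a density-scaled expectation (the offset can be disabled).
Environmental covariates — depth, sea-floor slope, seasonal mean SST,
distance to coast, distance to the 500-m isobath — attach by nearest raster
cell.

The GAM uses a log link with penalized cubic B-spline smooths (basis
dimension 10 before the sum-to-zero constraint, second-order difference
penalty — a P-spline stand-in for thin-plate bases, chosen for its banded,
exactly-known null space). Double-penalty selection adds a ridge on each
smooth's penalty null space so a term can shrink to zero entirely.
Smoothing parameters minimise a Laplace-approximate restricted marginal
likelihood evaluated with the **exact** compound Poisson–gamma series
log-likelihood; the Tweedie power is profiled over the grid
1.05–1.95 (step 0.05) with the dispersion φ optimised at each p, and the
(p, φ) profile alternates with λ selection until stable. λ search is
coordinate descent on a decade grid with joint per-term moves (a term only
leaves the model when range-space and null-space penalties grow together).
Deviance explained is 1 − D_model/D_null with the null model intercept +
offset at the selected p.

Family comparison fits Poisson, negative-binomial (moment-estimated
overdispersion) and Tweedie variants and ranks them by the
Shapiro–Francia normality of seeded randomized-quantile residuals — the
criterion that selects Tweedie for zero-inflated dolphin counts.
Zero-inflated Poisson is omitted by default: it was discarded in the
motivating analysis and its machinery is heavy relative to its value here.
Prediction rasters are scaled to 37-km² cells, flag extrapolation beyond
the training covariate range, and clip to the stratum polygons.

On recovery simulations (smooth of depth, Tweedie noise p = 1.4, n = 500
segments) the median correlation between fitted and true means exceeds
0.97 and the median edf of each irrelevant smooth is ≤ 0.5. Individual
fits can retain one weak ~1-edf spurious term; side-by-side runs of a
reference double-penalty selector on identical data show the same
behaviour, so tests assert medians over replicates, not single seeds.

## Synthetic surveys

The simulator reproduces the study conditions: four rectangular strata
with areas 9,042.2 / 21,026.8 / 5,103.6 / 7,265.2 km² (42,437.8 km²
total), systematic transects perpendicular to the coast at 7.5-km spacing
with a random start (≈5,500 km of effort), per-stratum densities spanning
the observed 0.004–0.24 animals/km², school sizes from a zero-truncated
Poisson with mean 2.0 capped at 20, and a double-platform observation
process P(platform j sees school) = p(0)ⱼ·g(x) drawn independently at all
distances — so point independence holds by construction and full
independence too, making the estimator's near-unbiasedness checkable.
Schools inside 71 m are visible to the mid seats only. Environmental
rasters are parametric: depth grows away from the northern coast with
smoothed noise, slope is its finite-difference gradient, SST carries a
coastal gradient whose sign flips between the summer and winter
configurations, and the distance layers are exact geometry. Geometry is
planar (km): at this spatial extent projection distortion is second-order
and every estimator is projection-agnostic.

What the simulator does *not* emulate: availability bias (animals diving;
deliberately not corrected, matching the motivating analysis), responsive
movement, observer heterogeneity beyond the two platforms, measurement
error in angles and school sizes, and real remote-sensing texture in the
covariates. Passing recovery tests therefore demonstrate internal
consistency of the estimators under the stated model, not robustness to
those field realities.

## Numerical choices and limitations

* Truncation intervals are closed ([left, right]); deterministic boundary
  behaviour.
* Detection covariates are centred/scaled on the training data; reported
  coefficients are on that scale.
* Detection fits refuse fewer than 10 sightings (configurable); GOF tests
  warn and skip below 5.
* The Tweedie series CDF sums the latent Poisson mixture to
  λ + 10√λ + 5 terms; the deviance is evaluated in its closed form.
* Replicate studies (coverage, recovery) are sized to desk scale — 200
  surveys for coverage, 100 replicates for recovery, 10 GAM fits — chosen
  as the smallest sizes at which the binomial noise of the rates is well
  inside the asserted bands.
* The detection variance component treats DS and MR parameter estimates as
  independent blocks (they are fitted to overlapping data); the shared-record
  correction is applied inside the MR p(0) variance, not across components.
* Density in reports is rounded to 2–3 significant decimals mirroring the
  field's table conventions; full-precision values are always in the JSON
  output.
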
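# Methods

This note documents the models, conventions and numerical choices
behind dielkit, and what its synthetic validation does and does not
establish about real camera-trap data.

## Solar geometry and the sun-anchored clock

Sun event times come from the NOAA solar-position equations (Meeus-style
polynomial ephemeris: geometric mean longitude/anomaly in Julian
centuries, equation of centre, apparent longitude with nutation and
aberration corrections, obliquity-based declination and equation of
time). Sunrise/sunset are the crossings of solar zenith 90.833°
(refraction plus solar radius) and nautical dawn/dusk of 102°; event
times are found by two fixed-point refinements of the ephemeris at the
current event estimate, which leaves well under a second of residual.
Timestamps are interpreted in site-local civil time with the UTC offset
resolved from longitude (round(lon/15) h). No pressure/temperature
refraction or topographic-horizon corrections are applied; within the
tropics these shift twilight boundaries by well under the ±2 min
tolerance the test suite enforces against an independently implemented
USNO-style almanac oracle.

The diel partition is half-open and exhaustive: day = [sunrise, sunset),
twilight = [nautical dawn, sunrise) ∪ [sunset, nautical dusk), night the
remainder. Morning twilight starts at *nautical* dawn, for symmetry with
nautical dusk: the night interval ends at nautical dawn, so any other
dawn definition would leave a gap in the partition. At latitudes where a
crossing does not exist the functions return an explicit missing value
or raise `PolarDayNightError`; nothing is silently defaulted.

Double anchoring maps sunrise to π/2 and sunset to 3π/2, interpolating
linearly within the daylight interval and within the night interval
(sunset to next sunrise) through 0 ≡ 2π. π is therefore solar noon and 0
solar midnight. For a fixed site the transform is a continuous bijection
from one *solar* day (sunrise to next sunrise) onto [0, 2π); note that a
single *civil* date contains the same night angle twice (late evening
and pre-dawn), so the inverse takes the solar-day anchor date, and
pre-dawn angles land on the following civil date. Round-trip error is
below one second. "Anchored hours" are the 24 equal arcs of this circle.

## Event construction

Species filtering keeps body mass strictly greater than 75 g and
stratum in {ground, scansorial}; a detection of a species missing from
the trait table is a hard error rather than a silent drop. Burst
collapsing is a greedy scan per species × camera: a photo is retained
iff its gap to the last *retained* event exceeds 1 h, which guarantees
retained events are pairwise separated by more than the window and
makes the filter idempotent. The alternative convention (gap to the
most recent photo of any kind) is available via `mode="photo"`.

Guild assignment applies the ≥ 0.80 diet-fraction thresholds in the
order vertebrate → plant → invertebrate, with everything else an
omnivore; fractions summing above 1 + 1e−6 are rejected. Size classes
use the 20 kg cut (small ≤ 20 kg < large), with species above 580 kg
marked `excluded`: they face negligible predation and drop out of the
coupling analysis only, never the diel model.

## Diel multinomial mixed model

The response is the event's diel category with day as reference, so the
night-vs-day coefficient direction *is* nocturnality. Both non-reference
categories share a fixed-effects design (candidate formulas: 1, logmass,
guild, logmass + guild, logmass × guild) and each has its own
protected-area random intercept, independent across categories with
separate variances. This keeps the per-area integral two-dimensional.

Estimation maximises the Laplace-approximated marginal likelihood in
the profiled form standard for GLMMs: the outer optimisation is over
(log σ_night, log σ_twilight) (L-BFGS-B, bounds [−6, 3]); for each
variance value an inner Newton solve maximises the penalised
log-likelihood jointly over fixed effects and area intercepts (analytic
gradient and Hessian, step-halving line search, gradient tolerance
1e−9, stricter than the 1e−6 the model's convergence contract states);
the Laplace log-determinant is taken over the random-effect block at
the joint mode. As the variances are forced to zero this objective
converges to the fixed-effects multinomial likelihood, which the tests
verify against an independent implementation (statsmodels MNLogit) to
1e−4. Final estimates are maximum likelihood and the model records
`stage="ML"`; no REML-style refit is defined for this family. Wald
standard errors come from the fixed-effects block of the inverse joint
Hessian at the optimum, AIC counts all fixed coefficients plus the two
variances, and a single-area fit falls back to fixed effects (variances
pinned at zero) with a warning.

Predictions are taken at the random-effect mode (a typical protected
area). Interval estimates use 1 000 draws of the coefficient vector
from its asymptotic normal distribution pushed through the softmax,
with 2.5/97.5 % probability quantiles — better behaved near 0/1 than
the delta method. Predictions outside the fitted log-mass range are
permitted but flagged `extrapolated`. Log base for mass is immaterial
to the model (the caller supplies the `logmass` column; the pipeline
uses natural log, the generator's ground truth is per decade, i.e.
log10 of mass in kg); slopes are reported on the scale supplied.

## Coupling GLMM

For a response/predictor group pair, hourly counts y_ah (area a,
anchored hour h) follow log E[y] = α + β x_ah + b_a with b_a ~ N(0, σ²),
fitted with the same profiled-Laplace scheme (1-D outer search over
log σ, bounded Brent). The predictor enters as the raw hourly count:
the standardized protocol equalises effort across bins within an area,
so no offset is used by default, and the printed effect sizes are per
predator event. Wald 95 % CIs call the direction: bottom_up if the CI
is above 0, top_down if below, none otherwise. The pairwise suite runs
all eight guild-size groups against large and small carnivores,
restricted to areas where large carnivores were detected; pairs with
fewer than 25 events in either group, or failed fits, are reported as
skipped/failed rows rather than dropped. σ² → 0 reproduces the
fixed-effects Poisson GLM to 1e−6 (tested against statsmodels GLM).

## Overlap coefficients

Activity densities are von Mises kernel estimates; the kernel
concentration follows the Ridout–Linkie plug-in rule
ν = (3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²))^{2/5} with κ̂ the von Mises MLE
(capped at 5 000 for near-degenerate samples), divided by the `adjust`
factor (0.8 for Dhat1, 1.0 for Dhat4, the conventions of the estimator
literature). Densities are evaluated on a 128-point grid (512 for
plotting and for the interpolation fallback) and renormalised so the
periodic trapezoidal integral is exactly 1.

Dhat1 integrates min(f̂, ĝ) on the shared grid; Dhat4 averages
min(1, ĝ/f̂) over one sample and min(1, f̂/ĝ) over the other, with
densities floored at 1e−12 and, for very large samples (n·m > 4·10⁶
kernel pairs), interpolated from the fine grid — the interpolation
error is orders of magnitude below sampling noise there. Dispatch uses
Dhat1 when the smaller group has fewer than 75 events and Dhat4
otherwise, following the estimator literature's recommendation (the
small-sample/large-sample wording in applied reports is sometimes
self-contradictory; both directions remain selectable). Estimates below
25 events per group warn.

Uncertainty: a smoothed bootstrap (resample a data point, add von Mises
kernel noise; 500 iterations) with a percentile interval shifted so the
bootstrap mean matches the point estimate; a naive resampling mode is
available. The null test refits the KDE to the pooled sample, redraws
both groups at their observed sizes, and reports the one-sided
proportion of null overlaps ≤ the observed one — small pNull means the
groups overlap less than same-distribution sampling explains. Regional
pooling across protected areas is deliberately not offered: pooling
heterogeneous sites inflates overlap.

## Synthetic generator

The generator emulates a standardized tropical survey: by default 8
protected areas spread over latitudes −20°…20°, 60 cameras per area
for 30 consecutive days, and a 20-species community with log-uniform
masses from 80 g to 300 kg. Guild proportions default to 45 %
herbivore, 25 % omnivore, 15 % carnivore, 15 % insectivore. Each
species' nocturnal weight is invlogit(a_g + s_g · log10 mass_kg) with
default slopes +1.0 (herbivore), +0.8 (insectivore), −1.2 (carnivore),
−0.5 (omnivore) — more nocturnal with size for herbivores and
insectivores, less for carnivores and omnivores — and intercepts 0 at
1 kg. The remaining weight splits (1 − c) : c between a diurnal and a
crepuscular component (c = 0.15). Activity mixtures are von Mises on
the anchored circle: nocturnal centred at 0 ≡ 2π, diurnal at π
(κ = 3), crepuscular split between π/2 and 3π/2 (κ = 8), matching the
anchoring convention and the estimator's kernel family. Visit times are
drawn on the anchored circle and inverted through the solar transform
for the site and date, guaranteeing round-trip consistency; each visit
emits a burst of 1 + Poisson(2) photos with exponential 2-minute gaps
so the independence filter has realistic work. Detection rates are free
parameters of the design (no published per-species values exist):
0.02 visits/camera-day/species with lognormal (sd 0.5) species
heterogeneity, chosen to give event counts per species-site in the
tens, typical of tropical forest surveys. Two out-of-scope decoy
species (arboreal, and sub-75 g) are appended by default to exercise
the filters.

`simulate_interaction` draws predator counts per site × anchored hour
as Poisson around a smooth nocturnal von Mises profile (mean 3 per bin)
and prey counts as Poisson with log-mean α_site + β·(predator count),
α_site ~ N(log 2, 0.3²), with β = ±0.2 or 0 by scenario.
`simulate_diel_categories` draws event-level categories directly from
the generating multinomial (Gaussian area intercepts, sd 0.3, on the
night logit), making the mass × guild model the exact generating
process for clean recovery studies.

What passing the synthetic suite shows — and what it does not: the
generator has perfect detection, no species misidentification, no
spatial structure within areas, no seasonal trend within a deployment,
and its activity mixtures are exactly von Mises. Recovery results
therefore validate the estimators and the pipeline plumbing, not
robustness to the messier failure modes of real surveys
(imperfect detection, rare-species sparsity, multi-year drift).

## Validation scales

The test suite and `scripts/acceptance.py` use problem sizes chosen as
a realistic desk-scale study: multinomial recovery at 10 000 events ×
8 areas (50 replicates in the test suite, 20 in the acceptance script),
coupling recovery at 11 areas × 24 hourly bins (100 replicates per
directional scenario, 200 for the type-I check), overlap validation at
n = 5 000 against an adaptive-quadrature oracle, and solar validation
on a 13-latitude × 12-month grid against the independent almanac
implementation. Published probability pairs (0.60/0.13 herbivore,
0.81/0.21 carnivore) are treated as inputs to the ratio computation.

## Known limitations

- The multinomial random intercepts are independent across categories;
  a correlated structure would need a 2-D covariance per area and is
  not implemented.
- Wald intervals throughout; profile-likelihood intervals would differ
  slightly for small-count coupling fits.
- The Laplace approximation is known to bias variance components
  downward with very few groups (< 5 areas); fixed-effect slopes are
  much less affected, as the recovery study shows.
- Timezones are nominal (longitude-derived); political timezones and
  daylight-saving rules are ignored, which only shifts the civil-time
  labels, not the solar geometry.
- Hourly counts aggregate all survey days within an area; no
  year-stratified variant is provided.
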
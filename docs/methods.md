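# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limitations of the `cardui` package.

## Collated abundance index

Transect visits are summed to site x year seasonal totals ("site counts";
visit effort is handled downstream as GLMM controls, not here). A Poisson
log-linear GLM with site and year main effects is fit to the totals; the
year effects, centered to mean zero across years, are the log-scale index,
so zero is the regional average for that season across the study years.

Two SE adjustments follow, neither of which moves the point estimates:

* **Overdispersion** — SEs are scaled by `sqrt(Pearson chi2 / df_resid)`,
  floored at 1 so a fortuitously underdispersed sample never deflates SEs.
* **Serial correlation** — the lag-1 correlation `rho` of within-site
  Pearson residuals across adjacent years is estimated, clipped to
  [0, 0.9], and SEs are multiplied by `sqrt((1+rho)/(1-rho))`. This is a
  working TRIM-style variance-inflation stand-in: the classical monitoring
  literature describes the adjustment without giving a single canonical
  estimator, so the package states its own and keeps it out of the point
  estimates entirely.

Season windows are inclusive at both ends: NE Spain spring 1 Mar-31 May and
summer 1 Jun-31 Jul (Mediterranean counts from August onward are excluded
as contaminated by southward return migration), NW Europe early summer
15 May-15 Jul and late summer 16 Jul-30 Sep. Autocorrelation checks compare
sample ACF at lags 1-4 against the white-noise bound `1.96/sqrt(n)` and are
run only on series longer than max(5, max_lag + 2) years; the linear-trend
test is an OLS F test (1, n-2) of the log index on year.

## Regional means and covariates

A grid cell belongs to a region iff its center lies inside the region
polygon (unambiguous at borders and the usual gridded-data convention).
Regional means over a month window are the mean of the per-month regional
means; cells are unweighted by default, with cos-latitude weighting
available (over the narrow latitude bands of single ecoregions the two
differ negligibly, and the classical grid-analysis tooling defaults to the
plain mean). Half-monthly composites collapse to months by arithmetic mean.
Covariates are standardized to zero mean and unit sample SD (ddof = 1);
constant series are an error, and standardization is idempotent.

## Kernel mapping

Per 1/12-degree cell, the Pearson correlation of one calendar month's NDVI
with the yearly log spring index is computed across years (>= 5 overlapping
years required), with the two-sided p from the t transform. Constant or
gappy cells are masked, never zero-filled. "Significant positive" means
r > 0 and two-sided p < 0.05; no multiple-testing correction is applied
because the map is exploratory and feeds confirmatory GLMMs. Cells are
assigned to the 1 deg square containing their center; a square is retained
iff it holds strictly more than 30 significant cells (edge squares with
fewer than 144 cells stay eligible under the same rule). The
northern/southern split is by square center against a configurable boundary
latitude (default 15 degN, approximating the Sahel/Sahara border, for which
no printed value exists).

## Poisson GLMMs

Counts are modeled as Poisson with log link; fixed effects are the
standardized yearly covariates (plus their products for interactions) and
the controls (standardized transect length and days recorded, never used as
offsets); crossed Gaussian random intercepts enter for Site_ID and Year
(categorical). The marginal likelihood is approximated by a Laplace
expansion around the joint mode of the fixed effects and spherical random
effects; the inner mode is found by damped Newton iterations on the concave
penalized log-likelihood and the outer optimization over the log random-
effect SDs uses Nelder-Mead. Wald SEs come from the fixed-effect block of
the inverse joint Hessian. The implementation reproduces lme4's `glmer`
Laplace fits to ~4 decimals on shared data (see the oracle test).

**Variance-component criterion.** By default the variance components are
estimated by a REML-type Laplace criterion that marginalizes the fixed
effects as well (adding the fixed-effect Schur complement to the
log-determinant), as in glmmTMB's `REML=TRUE`. With only ~20 year levels,
plain ML biases the year-level variance downward and with it the SEs of
year-level covariates, so Wald intervals undercover; the REML-type
criterion removes that bias. AIC is always reported on the ML scale (after
a REML fit a short ML polish of the variance parameters is run) so models
with different fixed effects remain comparable. `reml=False` restores the
plain ML fit.

The collinearity screen flags covariate pairs with pairwise |r| >= 0.7 and
model construction refuses them unless overridden. Stepwise deletion
removes, one refit at a time, the highest-p non-control term with
p >= 0.05, interactions strictly before their main effects, ties broken by
label order; controls and random intercepts are never dropped, and the
deletion trail is recorded. The battery runner isolates per-model failures,
reports delta-AIC within declared variant groups, and emits a
(model, term, sign, response) edge list of significant effects.

## Trajectory simulation

The six behavioral parameters and their defaults: airspeed 6.0 m/s;
heading due north regardless of wind; daily window 07:00-18:00 local solar
time (UTC + lon/15); at most 4 consecutive days, hence 44 flight hours;
activity threshold 10.0 degC at flight altitude; altitudes 1000/1500/2000 m
amsl (the level axis is read in the units the wind file declares); timestep
600 s.

Each day's flight window is fixed by the roost longitude at dawn, so a full
permissive day is exactly 11 h (66 steps) and 4 days log exactly 44 flight
hours; overnight the position is frozen (zero drift). Winds and temperature
are sampled by multilinear interpolation in (time, level, lat, lon); ground
velocity is wind plus the air vector, and positions advance by explicit
Euler steps on the sphere (`R = 6371 km`, so 111.195 km per degree of
latitude and a `cos(lat)` factor in longitude). At the default timestep the
endpoint of a 44-h uniform-wind track matches the closed-form solution to
well within 0.1% and halving the timestep moves endpoints by far less than
0.01 deg, so no higher-order integrator is warranted. A sampled temperature
below the threshold terminates the whole trajectory (the stricter reading
of cold termination; ending only that day's flight would be a one-line
variant), and leaving the data hull is a domain exit. Classification:
crossed if the track ever reaches the crossing latitude (28 degN by
default), else reached-north if a southern launch ends inside the northern
subregion, else failed; the check uses recorded vertices only, so it is
invariant to resampling. Batches launch one trajectory per kernel-square
center x date (07:00 local) x altitude and summarize counts per
year/month/altitude/category, with monthly success means and ranges.

The flight-boundary-layer feasibility helper converts
`(airspeed - headwind)` to km/h and reports
`distance / speed / hours_per_day` to 0.1 day, with an infeasible marker
when the headwind is not beatable.

## Synthetic generators

All generators take an explicit integer seed (NumPy PCG64), return their
ground truth alongside the data, and are bit-reproducible per seed.

* **Winds** (`gen_wind_fields`) — hourly u/v/T on a 1-deg grid (two level
  slabs bracketing the flight altitudes) over a 20 degW-20 degE x
  4-36 degN box. The `harmattan` scenario draws burst days i.i.d. with
  daily probability 0.15 and emits per-day constant fields: prevailing
  northeasterlies (u, v) = (-4, -6) m/s at 8 degC, or a southerly burst
  (2, 16) m/s at 22 degC. The cool prevailing air at flight altitude
  grounds migrants on non-burst days (they cold-terminate on their first
  step), which is the deliberate design: it makes the declared burst-day
  list an exact oracle — every simulated Sahara crossing must launch on a
  burst day. `uniform` and `solid_rotation` scenarios exist for integrator
  checks. These are caricature fields for oracle arithmetic, not reanalysis
  statistics.
* **NDVI** (`gen_env_grids`) — monthly 1/12-deg grids; inside planted
  kernel squares each cell's standardized year series is
  `r x latent + sqrt(1 - r^2) x noise` (target correlation r = 0.8 by
  default, 22 years), independent noise outside; NDVI is an affine map
  (0.30 + 0.08 z) clipped to the valid [-0.3, 1] range. A target |r| >= 1
  is a config error.
* **Counts** (`gen_transect_counts`) — per region x season: default
  30 sites with lengths uniform on 1-5 km, weekly visits inside the season
  window, log-mean = beta0 + beta.x_year + 0.3 x standardized length +
  site intercept (SD 0.3) + year intercept (SD 0.2) + log phenology weight.
  Phenology is a Gaussian bump per season (the NW Europe pair forms the
  bimodal early/late pattern with the larger August peak), normalized to
  mean 1. Overdispersion is gamma-mixed Poisson (negative binomial) with
  configurable size; the full-study default is size 8 (mild), single-set
  generators default to pure Poisson. The site/year SDs and effect sizes
  were fixed once at values giving the order-of-magnitude interannual
  swings the monitoring series show.
* **Study chain** (`gen_study`) — standardized stage drivers
  latent -> spring -> summer -> NW-early -> NW-late, each link
  `c x previous + sqrt(1 - c^2) x noise` with c = 0.8; the same latent
  series is planted in the NDVI kernel, and each stage drives one count
  set's year intercepts (plus SD 0.15 noise).

What passing tests on these data do **not** show: the generators have no
coastlines, orography, spatially correlated noise, observer effects, or
missing visits, so recovery rates here are upper bounds on what real
monitoring and reanalysis data would support.

## Problem sizes and determinism

The statistical acceptance checks use 100 seeded replicates for GLMM
recovery, stepwise deletion and type-I control, 20 seeds for kernel
recovery on an 8 x 6 deg NDVI domain, and three 50-day harmattan batches —
sizes chosen so the whole suite reruns on a laptop-class single core in a
few minutes while leaving comfortable Monte-Carlo margins around each
threshold. The type-I criterion is assessed as the pooled per-term
false-positive rate across the battery (expected ~5% at alpha = 0.05).
Stepwise ties are broken by label order; all optimizer starting points are
fixed; the pipeline manifest hash excludes timestamps so identical
config + seed reruns are verifiably identical.

## Known limitations

* The GLMM engine fits crossed random intercepts only (no slopes, no
  spatial fields, no zero inflation) — all the battery needs.
* The serial-correlation SE inflation is a stated stand-in, not a
  reconstruction of any particular monitoring package's estimator.
* The trajectory model is deliberately indicative: fixed altitude, no
  vertical winds, no fuel bookkeeping beyond the 44-h cap, no stochastic
  behavior; real migration pathways would differ.
* Real-data headline figures (e.g., absolute crossing percentages over a
  12-year reanalysis archive) require the original wind archives and count
  deposits and are outside what the synthetic suite can or does reproduce.
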
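# Methods

`coarselur` builds spatial prediction models for coarse particulate matter
(PM10-2.5, particles of 2.5-10 um aerodynamic diameter) from snapshot
monitoring campaigns: simultaneous two-week filter samples collected outside
~40 residential sites per city, in two seasons, with paired PM10/PM2.5
impactors. Because no public data exist for such campaigns, the package
includes a synthetic-campaign generator with a known ground truth, and every
modelling stage is validated against that truth.

## The model

Concentrations at site *s* in season *t* are modelled as

    y(s, t) = b0 + sum_j b_j x_j(s) + g * season(t)
              + sum_k c_k x_k(s) * season(t) + eta(s) + eps(s, t)

where `x_j` are GIS-derived covariates summarised in circular buffers around
the site (land use, road lengths, imperviousness, vegetation, population,
emissions), `season` is an indicator, `eta` is a spatially correlated
residual, and `eps` is unstructured error. **Land-use regression (LUR)**
fits the fixed part by ordinary least squares and ignores `eta`.
**Universal kriging (UK)** is realised two-stage: fit the LUR, fit an
exponential variogram to its residuals, and add a simple-kriging
interpolation of those residuals to predictions. The two-stage form (rather
than simultaneous GLS) keeps cross-validation folds simple and is a standard
approximation at campaign scale (n ~ 40-60 per city); it is exact in the two
degenerate limits tested (zero partial sill reduces UK to LUR; zero nugget
interpolates the training data).

Pooled multi-city models add a city indicator and covariate-by-city
interactions, and are evaluated per city against each city's own mean, which
asks whether the pooled model captures *within-city* contrasts rather than
between-city level differences. Negative per-city R2 values are reported as
0 (the raw value is retained in the report).

## Quality control

A sample pair is voided when any of the following holds, with reasons
assigned in this fixed precedence: sampling duration < 9 days; pump flow
deviation beyond +/-20%; damaged filter (input flag); coarse mass more than
5 SDs from its city-season stratum mean; coarse-fraction sulfur > 0.2 ug/m3
(sulfur resides almost entirely in the fine fraction, so its presence in the
coarse channel indicates a sampling artifact). The outlier screen uses the
stratum mean/SD of the candidate set surviving the earlier rules, computed
in a single pass — statistics are not recomputed after removals. A
consequence worth knowing: the standardised deviation of a point within its
own stratum is bounded by (n-1)/sqrt(n), so a 5-SD rule can only ever fire
in strata of at least ~28 candidates, and two simultaneous gross outliers in
a small stratum can mask each other. The separate 3-SD outlier exclusion is
a modelling-time sensitivity switch, not a QC rule.

Coarse mass is PM10 minus PM2.5 from collocated samplers; negative
differences are retained but flagged. Duplicate precision is the median of
|a-b| / pair-mean over collocated duplicate pairs.

## Covariate screening

The raw library (hundreds of columns) is reduced deterministically:

1. drop columns whose 85th percentile equals their 15th percentile
   (linear-interpolation quantiles, computed on the analysis rows);
2. per buffered category, keep at most one short-range buffer (50-500 m,
   inclusive) and one long-range buffer (> 500 m) — the buffer with the
   largest absolute Pearson correlation with the outcome. The long range is
   left uncapped because the library carries buffers beyond 5 km (truck
   routes, population, emissions) that would otherwise never be screened;
3. among columns mutually correlated at |rho| > 0.85, resolve each connected
   component greedily: prefer non-positional over positional covariates and
   raster-2000 land use over 1970s aerial-photography land use, then keep
   the largest |r(x, y)|, drop its over-threshold neighbours, repeat.

Ties in |r| break toward the smaller buffer radius, then lexicographic name.
Every decision is recorded in a trace that accounts for every input column.

## Model selection

Survivors (plus the season indicator, covariate to season interactions, and
in pooled scope the city indicator and covariate x city interactions) enter
a LASSO path of 100 log-spaced penalties, from the smallest penalty that
zeroes all coefficients down to 1e-4 of it, on internally standardised
columns. The candidate set is the largest LASSO support with at most 15
terms. All subsets of at most 6 parameters are then enumerated — the
intercept is free; each main effect, the season/city indicator, and each
interaction counts one parameter, even when a categorical indicator spans
several design columns. A subset containing an interaction without its main
effects is repaired by forcing the main effects in; repair may exceed the
6-parameter cap (the cap applies at enumeration). Each candidate is fit by
OLS under one shared random 10-fold split (fold sizes differ by at most
one); rank-deficient candidates are discarded. The winner minimises
cross-validated RMSE on pooled held-out residuals, with ties (delta RMSE
< 1e-10) broken by fewer parameters, then lexicographic term names.

CV R2 is 1 - SSE/SS(mean) on the pooled held-out predictions, not a squared
correlation; the squared correlation between observations and predictions is
reported separately as a diagnostic. In UK mode the variogram is refitted
inside every training fold so no held-out information reaches the kriging
weights.

Two sensitivity switches rerun the identical pipeline: natural-log
transformed concentrations (values floored at 0.05 ug/m3 before the log),
and exclusion of samples beyond 3 SDs of their city mean. With both off the
run is bit-identical to the primary analysis.

## Variogram estimation

Two estimators are provided.

* `fit_variogram` (default, used inside UK): empirical semivariances in ~12
  equal-count lag bins up to half the maximum pairwise distance, exponential
  model `gamma(h) = nugget + psill * (1 - exp(-h/range))` fitted by weighted
  least squares with pair-count weights. Because equal-count binning lumps
  all short lags into one wide bin — exactly where nugget and short-range
  sill are distinguished — the first bin is subdivided into four equal-count
  sub-bins. The fit is multi-started (nugget-dominant, balanced,
  sill-dominant) and numerical ties resolve toward the nugget-dominated
  solution: a flat semivariogram is evidence of no spatial structure, and
  the fit should not claim any. The range is bounded above by the maximum
  binned lag. The effective range (95% of the sill) of the exponential model
  is about 3x the range parameter.
* `fit_variogram_ml`: Gaussian maximum likelihood on the full covariance
  (Nelder-Mead over log-parameters, two starts). It is markedly more
  efficient for parameter recovery — in the package's recovery experiments
  it roughly halves the median relative error of the range — at O(n^3) per
  likelihood evaluation, so it suits one-shot estimation rather than the
  inner CV loops.

Kriging solves use a Cholesky factorisation with two guards: repeated
site-seasons share coordinates, so a zero fitted nugget makes the system
exactly singular (ridge jitter + minimum-norm solve), and a near-singular
system that slips through the factorisation is caught by an interpolation
bound — kriged residuals cannot exceed twice the largest training residual
in magnitude — and re-solved with a larger ridge.

## The synthetic campaign generator

The generator emulates the study conditions: three cities on 30 km square
domains with 10 km urban cores, 40 sites per city (half placed in the core),
two seasons, and both-season repeats at a third of sites (the thinning
happens before defect injection so QC sees the same strata the ledger was
built against). Buffered covariates are disk averages of a shared latent
Gaussian-bump surface per category, which reproduces the nested-buffer
correlation of real GIS extractions (100 m and 300 m buffers correlate more
strongly than 100 m and 5000 m). Coarse mass is the linear predictor on
z-scored covariates (default: five active covariates with coefficients
0.4-0.9 ug/m3 per SD, intercept 4.5 ug/m3, summer offset 0.8 ug/m3, one
season interaction) plus an exponential-covariance field (range 3 km, sill
0.4, nugget 0.4 by default) drawn exactly via Cholesky, plus
lognormal-multiplicative measurement noise (sigma 0.10; an additive Gaussian
option exists for closed-form coefficient-recovery oracles). Negative
concentrations are truncated at 0 and counted. PM2.5 is drawn independently
and PM10 = PM2.5 + coarse, so subtraction recovers the generated coarse mass
exactly. Four trace species (copper, zinc, phosphorus in ng/m3; silicon in
ug/m3) share the spatial mechanism through species-specific couplings.

QC defects are injected at configurable per-sample rates (defaults: 5% each
for short duration, bad flow, high sulfur; 2% outliers), at most one defect
per sample, with the kept defect following QC precedence so ledger reasons
match report reasons. Gross outliers are injected at most once per
city-season stratum and only into strata of at least 30 clean candidates,
for the (n-1)/sqrt(n) detectability reason above — this is what makes "the
voided set equals the ledger" a well-posed exact oracle.

What the generator does **not** emulate: real GIS geometry (roads, rasters,
dispersion fields), targeted site selection (sites are uniform within
strata, not chosen to maximise covariate contrast), temporally varying
spatial fields within a season, correlated defect mechanisms, or
non-Gaussian residual fields. Passing recovery tests therefore demonstrates
that the statistical machinery is correct under the stated generative model,
not that the models transfer to any particular real airshed.

## Validation experiment sizes

The recovery experiments (in `coarselur.validation`, driven by both the
acceptance tests and `scripts/acceptance.py`) use: 50 campaigns of 500
samples for coefficient recovery against the closed-form OLS sampling SD;
20 field-scale campaigns (~60 samples, residual structure set so the
generating model's oracle R2 is about 0.6 — sill 0.7, nugget 0.7, noise
sigma 0.12) for selection sanity; 20 nugget-dominated campaigns (sill 0.08,
nugget 0.7) for the UK-LUR comparison, the regime in which the two should
agree; 20 fields of 500 points (range 2 km, sill 1, nugget 0.1) for
variogram recovery; and 20 defect-injected campaigns of 45 sites for the QC
ledger oracle. The published two-season summary statistics serve as
worked-example inputs for the pooled-summary arithmetic; note that because
the published per-season inputs are rounded to two decimals, one of the
three pooled city means re-rounds 0.01 low.

## Known limitations

* UK is two-stage, not GLS: coefficient estimates ignore residual
  correlation, which mainly affects their standard errors (not computed).
* The LASSO counts active design columns per term; a city indicator's
  dummies enter the penalty separately rather than as a group.
* Kriging variance is not computed; predictions are point values.
* Grid predictions are not truncated at zero by default (an export option
  clips them), so linear-model extrapolation can produce negative
  concentrations at covariate extremes.
* The moment-based variogram fit has substantial sampling variability in the
  range parameter; use the ML fit when the parameter values themselves
  matter.
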
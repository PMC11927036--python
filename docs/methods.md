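# Methods

`aidimpact` estimates the effect of sustained, broad, above-median donor
health funding on mortality among women of reproductive age (WRA, ages
15–49), from country-year panels. This note documents the models, the
defaults and why they were chosen, the behaviour of the synthetic-data
generator, and the numerical decisions a maintainer would want to know.

## Outcome and cohort definitions

The outcome is the WRA mortality rate: deaths among women aged 15–49 per
1,000 WRA per year, recomputed from raw counts whenever both are present.
The denominator is taken as the (mid-year) WRA population as supplied; no
person-time refinement is attempted.

The treated unit is an aggregate of the countries that received (a)
positive funding in every year of a sustained-funding window (default
2007–2019), (b) funding across a broad range of health programme areas —
this cannot be derived from an aggregate funding column, so it enters as a
user-supplied boolean flag per unit — and (c) per-unit mean annual total
*and* per-capita funding strictly above the medians of the funded reference
set. "Above median" is strict `>` by default (configurable): borderline
units sitting exactly at a median are excluded, which matters because
inclusion decisions at the margin change the aggregate.

The aggregate outcome is total member WRA deaths over total member WRA
population, i.e. the per-year population-weighted mean of member rates.
Predictors are aggregated the same way, except logged total population,
which is the log of the summed population (the aggregate acts as one large
country, not an average-sized one). Whether the weighting should instead be
unweighted is genuinely open; population weighting was chosen for
consistency with the outcome construction.

Donor-pool filtering applies six sequential screens, each logged with
per-unit reasons: baseline income class; not treated-like in funding
exposure; population of at least 500,000 in the year before treatment (a
single-year rule, treatment year − 1); an ascending pre-period trend in the
*share* of WRA deaths among total deaths (OLS slope strictly positive, with
a float-noise tolerance so flat series never pass); existence (non-missing
outcome) over the full pre-period; and non-missing HIV prevalence over the
pre-period. Units with fewer than three finite share points are deferred
from the trend screen to the existence screen, which is where such units
fail anyway — this keeps "too new to evaluate" and "evaluated and
non-ascending" distinguishable in the report.

Missing predictor values are linearly interpolated within a unit's series
only between observed points; edge gaps are flagged, never extrapolated,
so downstream screens can exclude the unit explicitly.

## Synthetic control

Given treated predictor means `X1` (per-predictor pre-period means,
scaled to unit standard deviation across units so importance weights are
comparable), donor predictor matrix `X0`, and pre-period outcome paths
`Z1`, `Z0`, the estimator solves the nested program

    inner:  W(V) = argmin_{W ≥ 0, ΣW = 1} (X1 − X0 W)' diag(V) (X1 − X0 W)
    outer:  V*   = argmin_{V ≥ 0, ΣV = 1} RMSPE(Z1, Z0 W(V))

The inner problem is a convex QP solved as penalised non-negative least
squares (the adding-up constraint enters as a heavily weighted row; exact
in the limit), with a small ridge term (1e-4 on the design scale) that
makes the solution unique — and continuous in V — when the weighted
predictor system is rank-deficient, as happens when V approaches a vertex.
Without the ridge, the inner solution at a vertex is an arbitrary member of
a solution set and the outer loss becomes discontinuous there. An optional
SLSQP polish refines the reported solution. Donor weights below 1e-4 are
truncated to zero and renormalised for reporting.

The outer loss is minimised by Nelder–Mead over softmax-parameterised V
from a fixed multi-start list: uniform V, the regression-based V of the
synthetic-control literature (predictor importances proportional to squared
coefficients from regressing pre-period outcomes on predictors across all
units), one start per single-predictor vertex, and seeded Dirichlet draws
(4 by default), followed by one restart from the incumbent. Ties go to the
earlier start. The whole fit is deterministic for a fixed option set.
Because the softmax search lives in the open simplex, exact-boundary V is
reachable only by underflow; the outer optimum is therefore understood as
an interior optimum, which is also what the ridge-regularised inner
problem makes well-posed.

Per-year effect estimates are gaps (treated minus synthetic); the average
treatment effect is the unweighted mean of post-period gaps, with an
optional second summary over a caller-supplied subset of years (e.g. the
placebo-significant years).

## Placebo inference

Each donor is refitted as a singleton pseudo-treated unit against the
remaining donors. The p-value for a year is the share of placebo units
whose absolute gap is at least as large as the treated unit's, so p-values
live on {k/J}. Ties count against the treated unit. Standardised p-values
divide every unit's gaps by its own pre-period RMSPE before ranking, which
discounts placebos whose post-period gaps merely continue a bad pre-period
fit; placebos with an exactly zero pre-period RMSPE are excluded with a
warning. The post-average p applies the same rank rule to mean post-period
gaps. No RMSPE-based trimming of poorly fitting placebos happens by
default. A p of exactly zero renders as "<0.001" in human-readable output
but is stored as 0.0.

## Bayesian latent-factor counterfactual

The model is

    y_it = μ + β'x_it + α_i + ξ_t + γ_i'f_t + ε_it,   ε_it ~ N(0, σ²)

fitted by a Gibbs sampler on all donor cells plus treated pre-period cells;
treated post-period cells are imputed from the posterior predictive
(including observation noise) as counterfactuals. Priors: N(0, 10²) on μ,
on standardised-scale β, and on loadings; hierarchical N(0, τ²) on unit
and year effects with InverseGamma(2, 1) on each τ² and on σ²; N(0, 1) on
factor coordinates. Predictors are internally z-scored for sampling and
coefficients are mapped back to the original scale on storage. Defaults:
2 factors, 4,000 iterations, 2,000 burn-in, thinning 2, 90% equal-tailed
intervals. Unit- or time-varying covariate coefficients are not
implemented; the latent factors already absorb unit-specific responses to
common shocks at this problem scale.

Factor models are rotation-invariant, so stored draws are put in a
canonical form purely for interpretability: factors centred over fitted
years (shift absorbed into unit effects), columns orthonormalised by QR,
sign fixed by the first unit's loading. Counterfactual draws are computed
before this transformation and are invariant to it.

Aggregate per-year effects are observed-minus-counterfactual draws combined
over treated units with per-year WRA-population weights; the post-period
average is a posterior functional (post-year mean within each draw, then
summarised across draws), which is not generally the average of the yearly
summary rows. Per-country summaries flag units whose intervals overlap
zero.

In the exact noiseless limit the posterior predictive cannot collapse to a
point because the variance priors are proper (InverseGamma(2, 1) keeps σ²
of order 1/n even at zero residual error); noiseless-limit checks therefore
use tolerances of a few hundredths of a death per 1,000 rather than machine
precision, and additionally cross-check against a closed-form two-way
least-squares fit.

## Sensitivity battery

*Scenarios* re-run the pipeline with named countries removed from the
treated aggregate; funding thresholds are kept at baseline by default so a
scenario isolates composition effects. *Residual regression* is a two-step
procedure: a single pooled OLS (all units, all years, with intercept) of
the outcome on non-USG ODA per capita, then the full estimator re-run on
the residual outcome. The regressor is configurable; the default is the
competing (non-USG) stream, since the point of the exercise is to net its
effects out of the outcome before re-estimating the USG effect. The
summary is the ratio of residual to baseline ATE: ≈1 means the competing
stream does not bias the baseline, below 1 partial influence, above 1 a
downward bias of the baseline. *Treatment-year scan* refits over candidate
years, skipping any that leave fewer than five pre-period years. *Split
placebo* truncates the panel to the pre-period, trains on the first half
(split at floor(T0/2)) and predicts the second half; a well-specified model
finds no effect there.

## Deaths-averted accounting

Lives saved in a year are `−effect × WRA population / 1,000`; harmful years
come out negative and are not clipped. The non-USG adjustment multiplies by
`(1 − share)`. All arithmetic is full precision internally; integer
rounding happens only at report boundaries, and window totals in millions
round to one decimal. No uncertainty propagation from effect intervals is
attempted; ranges across methods are the intended uncertainty statement.

## Synthetic-data generator

Untreated outcomes follow the latent-factor model above with a hump-shaped
common year effect (rising from 1990 to a peak near 2003, then declining —
the qualitative trajectory of WRA mortality in heavily aid-funded
countries), unit intercepts of SD 0.7 around a base rate of 6 per 1,000,
AR(1) factors and covariates, and Gaussian noise (SD 0.15 by default).
The injected effect is zero before the treatment year and ramps linearly
to −1.0 deaths per 1,000 by 2014, then stays flat, roughly the magnitude
scale of the published estimates. Treated funding has a sharp post-2004
level jump and is above both medians by construction; donor funding is
sporadic (a few funded years) with total and per-capita window means
*anti-ranked* across donors, so that no donor exceeds both medians — this
makes cohort-selection closure exact rather than probabilistic. Death
counts are derived from rates and integer-rounded by default (the
rate/count identity then holds to rounding error; generators used in
exactness tests disable rounding). Rates that would go negative are
clipped at zero and counted in the ground-truth record.

The generator matches the Bayesian model class, so that model is
well-specified by default; a mis-specification switch adds an accelerating
trend to treated units only (a common trend would be absorbed by the year
effects and is not a mis-specification any of these estimators can feel).
What the generator does *not* emulate: measurement error and revisions in
real mortality series, spatial correlation between neighbouring countries,
structural breaks (wars, epidemics) except via the generic factor shocks,
and funding endogeneity (funding responding to mortality). Passing tests
therefore demonstrate correctness of the estimators under their assumed
model, not robustness to everything real data can do.

The cohort fixture engineers extra units that each fail exactly one screen
so the attrition path reproduces the target counts 77 → 59 → 23 → 19
(16 treated selected, 19 donors surviving), including a unit established
after the study start and units with missing HIV series.

## Problem sizes used in the test suite

Simulation-heavy checks run at reduced scale, chosen as the smallest
configurations that still exercise the relevant asymptotics: placebo
validity uses 1 treated + 19 donors over 1997–2012 with 200 replicates;
Bayesian calibration uses 4 treated + 10 donors over 1995–2014 with one
factor, 2,000 Gibbs iterations and 100 replicates; the split placebo uses
30 replicates per specification; the residual-ratio null uses 100
replicates with the ratio computed as the ratio of summed ATEs across
replicates (individual ratios are heavy-tailed when a replicate's baseline
ATE is near zero). Reduced-cost optimiser settings (fewer starts, no
polish) are used inside replicated simulations; they leave permutation
symmetry intact, which is all those checks require.

## Known limitations

* The outer V-optimisation is a heuristic over a non-convex landscape;
  different start lists can settle on different V with nearly equal
  pre-period fit. Only the fit (RMSPE) and the resulting gaps are treated
  as interpretable, not V itself.
* The Gibbs sampler assumes homoskedastic noise across units and years.
* Cohort selection treats funding units as opaque and consistent within a
  panel; no currency or deflator handling.
* The split-placebo check loses half the pre-period and is accordingly
  noisy on short panels.
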
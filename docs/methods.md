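# Methods

This note records the statistical model, the synthetic-cohort generator,
the numerical choices, and the design decisions that were genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Outcome scale and model

Gestational weight gain (GWG) at a visit is the measured weight minus
pre-pregnancy weight, in kg.  Gains can be negative (early-pregnancy
weight loss is common), so the outcome is shifted by a constant 20 kg
before the log transform: `y' = log(y + 20)`.  The shift makes every
plausible value positive (the implausibility filter removes gains under
−10 kg), stabilises the variance, and turns covariate effects into
multiplicative factors on `y + 20` — which is how coefficient tables are
reported (`exp(median)` to 3 decimals).

Per pre-pregnancy BMI stratum the model is a hierarchical
(mixed-effects) regression:

    y'_ij = β₀ + f(GA_ij) + γᵀX_ij + τ_i + ε_ij,
    τ_i ~ N(0, σ_τ²),    ε_ij ~ Student-t(ν, 0, σ_ε)  (or N(0, σ_ε²)),

with f a natural cubic spline of gestational age with five degrees of
freedom.  The random intercept τ_i carries the strong within-woman
correlation of repeated gains; the Student-t error resists the occasional
transcription-style outlier.  Priors:

| parameter | prior | rationale |
|---|---|---|
| β₀ | N(3, 1) | 3 ≈ log 20 is zero gain; SD 1 is a multiplicative factor e ≈ 2.7 on y+20, wide but excludes impossible values |
| β_k (spline), γ (per dummy) | N(0, 1) | weakly informative on the log scale |
| σ_τ, σ_ε | half-Student-t(3, 0, 1) | standard weakly-informative scale prior; the source analysis wrote "σ² ~ Student-t(3,0,1)", which its software family interprets as a half-t on the SD — we follow that convention |
| ν | Gamma(2, 0.1), truncated ν > 2 | the t degrees of freedom are never reported; truncation keeps the error variance finite |

The random intercept is Normal with a half-t-hyperprior scale; a prose
description elsewhere calls τ "cauchy", but the model equation (Normal
with estimated scale) is what is implemented.  Reference levels for the
dummy coding are age ≥35, height ≥162 cm, multipara, never-smoker, no
previous disease; the "missing" answers for smoking and previous disease
are explicit non-reference levels, so missingness is a modelled category
rather than a dropped row.  Parity is included as a covariate (it appears
in the published coefficient table even where a prose list omits it).

## Spline basis

The basis is the *cardinal* form of the natural cubic spline space: with
nodes `t₀ < … < t_df` (two boundary knots plus df−1 interior knots), basis
function k is the unique natural interpolating spline of the unit vector
e_k; the function attached to t₀ is dropped, so the basis has no constant
column (the intercept is separate) and vanishes at the lower boundary
knot.  Values outside the boundary are linearly extrapolated from the
boundary value and slope — the defining natural-spline property, and the
reason this family was chosen: charts extend past the bulk of delivery
measurements and a linear tail is the only defensible extrapolation.

Knots are placed at equally spaced quantiles of the observed gestational
ages with boundary knots at the observed range (standard practice when
only the df is prescribed; the source analysis does not state its knots,
and no result here depends on their exact position).  Tests verify the
basis against an independent truncated-power construction (max abs
difference < 1e-8 over random knot sets), C² continuity at interior
knots, vanishing second differences beyond the boundary, and exact
reproduction of linear functions.

## Sampler

No general-purpose MCMC PPL is a dependency; the model's conditional
structure admits an efficient special-purpose Metropolis-within-Gibbs
sampler:

1. **Scale-mixture weights.**  ε ~ t(ν, 0, σ_ε) is represented as
   ε | w ~ N(0, σ_ε²/w), w ~ Gamma(ν/2, ν/2); w is conjugate.
2. **Regression block, collapsed.**  Given w, the marginal covariance of a
   woman's visits is diag(σ_ε²/w) + σ_τ²·11ᵀ, block-diagonal per woman, so
   Woodbury gives the exact Gaussian conditional for the full coefficient
   vector (intercept, spline, γ) with τ integrated out.  Collapsing
   removes the β₀ ↔ mean(τ) random-walk coupling that otherwise dominates
   the autocorrelation time.
3. **Random intercepts.**  τ_i | β, w is Gaussian, updated vectorised.
4. **Scales and ν.**  σ_ε and ν are updated by univariate slice sampling
   (stepping-out + shrinkage, on log coordinates) against the *exact*
   Student-t likelihood of the current residuals (w integrated out, which
   decouples them from the latent weights); σ_τ likewise against the τ
   vector.  Slice sampling is tuning-free and exact, which keeps the
   sampler free of step-size heuristics and of divergent transitions
   (the divergence count in diagnostics is identically zero).

Chains are initialised over-dispersed around a ridge least-squares fit so
split-R-hat is meaningful.  With an empty design the same loop samples
the prior (used by the prior-recovery test).  Desk-scale default: 4 chains
× (500 warmup + 1,000 draws), which on simulated strata of 300–8,000 women
yields minimum bulk ESS in the high hundreds to thousands and R-hat ≤ 1.01;
the production recommendation for accurate HDIs (ESS ≥ 10,000, as in the
source analysis's 52,000–60,000-sample runs) is a diagnostics threshold
option, not the default.  Reproducibility: a fit is deterministic given
(data, SamplerConfig.seed); permuting row order changes the latent-variable
random stream, so summaries agree only to Monte-Carlo precision.

Posterior summaries report the median, exp(median), posterior SD, 95%
highest-density interval (narrowest interval; computed by direct scan over
sorted draws) and bulk ESS.

## Synthetic cohorts

The generator is the package's study population.  What it emulates, per
the published cohort description: the BMI-category mix (16.1/73.2/8.2/2.5%),
per-stratum covariate frequencies taken from the published descriptive
table (including the "missing" answer frequencies), four visits —
early/mid/late/delivery — with timings 11.1 (1.8), 23.3 (2.9), 32.8 (3.0),
38.8 (1.6) weeks inside the clinical windows (early 1–15, mid 16–28, late
29 to just before delivery, delivery 32–43), the completeness pattern
(complete 86%, missing delivery 8%, missing third 4%, missing second 1%,
missing first 1%, never below three visits), and GWG drawn from the model
above.

Numerical detail: a truncated normal's mean is shifted from its location
parameter, by up to ~0.4 weeks for the mid/late windows.  The generator
therefore root-finds a location offset per visit type so the *population
mean* timing equals the configured mean (for the late visit, whose upper
bound is each woman's delivery time, the match is on the average across
women).  Tests check all configured moments at n = 10,000 within 3
Monte-Carlo SEs.

Ground truth per stratum: γ and σ_τ are the published posterior medians
(bundled in `gwgcharts/data/reference_effects.csv`); β₀ and the spline
coefficients are calibrated so the reference-profile median curve passes
through the published 50th-percentile chart values at 10/20/30/40 weeks
plus zero gain at conception.  Two calibration routines exist:
`calibrate_median_spline` does exact least-squares interpolation (the
contract tests rely on: ≤ 6 anchors are reproduced exactly), while the
default truth uses `smooth_anchor_projection` — a monotone PCHIP
interpolant of the anchors projected onto the basis — because exact
interpolation of 5 anchors in a 6-parameter space is underdetermined and
produced plateaus and dips between anchors that no observed pregnancy
series shows (anchors are then reproduced to ~0.1 kg).

Unreported quantities are calibration choices, made once: the residual
scale σ_ε per stratum (0.039/0.038/0.042/0.056) was solved so that the
10th–90th predictive spread at 40 weeks matches the published chart
spread per stratum; the error df is 3 (matching the scale hyperprior's
df); the coefficients of the "missing" covariate levels (absent from the
published table) are small positive values in line with the descriptive
table (0.03 smoking, 0.01 disease).

What the generator does **not** emulate: GA dating error, self-report bias
in pre-pregnancy weight, covariate–visit-schedule dependence, pregnancy
complications and delivery mode (used upstream only to define a low-risk
subset), and any model misspecification — the data are generated by the
model being fitted.  Passing recovery/calibration tests therefore
demonstrate the *correctness of the machinery*, not that the model is
adequate for a real registry.

## Charts, bands, validation

**Charts.**  Per grid week (integer weeks 8–42), predictive samples are
drawn as: random posterior draw, covariate profile from the stratum's
empirical per-woman mix (a fixed reference profile is an option), fresh
τ\* ~ N(0, σ_τ), residual from the error family, back-transformed to kg.
Percentiles use the linear-interpolation estimator on sorted samples
(noted because extreme percentiles are estimator-sensitive).  Percentiles
of a common sample set are monotone in the level by construction; the
invariant is re-checked after smoothing.  Smoothing fits a cubic
smoothing spline per percentile across weeks, with the roughness budget
set from a third-difference noise estimate (third differences cancel
smooth trend up to quadratics); if smoothing ever breaks cross-percentile
ordering, an isotonic repair is applied and a warning raised.  The
maximum absolute change due to smoothing is recorded in the chart's
provenance.  Weeks outside the observed GA range rely on the spline's
linear extrapolation.

**Bands.**  The guideline endpoints at 40 weeks are inverted through the
chart (linear interpolation across the percentile dimension — the same
interpolation used to evaluate the chart, so inversion and evaluation are
exact inverses) and the two resulting percentile curves are followed
across the grid.  How the original analysis derived its ranges is not
stated; this invert-then-follow rule is the natural reading of "ranges of
trajectories that meet the guidelines" and is the package's documented
interpretation.  Week-40 anchoring to the guideline interval within 1e-6
kg is a hard invariant; the obese band is one-sided (upper only) because
its recommendation is "at most 5 kg".  `fraction_within_band` takes each
woman's last measurement at ≥ 37 weeks (configurable) and compares it with
the band interpolated at that gestational age; on model-generated data the
fraction equals the percentile mass between the band's anchors.

**Validation.**  Train/test splits are always by woman (τ_i correlates a
woman's visits; splitting rows would leak).  Coverage is evaluated per
observation — the chart is used clinically against single measurements —
with exact binomial (Clopper–Pearson) intervals per level, and the "fit"
verdict is that every level's CI contains its nominal fraction.  A caveat
the binomial intervals ignore: observations within a woman are correlated,
so the effective sample size is closer to the number of women than the
number of rows.  For the calibration check in the acceptance suite the
held-out set is therefore sized at 2,000 women (~7,700 observations; an
80/20 split of a 10,000-woman stratum), at which the ±0.02 coverage
tolerance at the median corresponds to roughly two SDs of the coverage
statistic under the generative model.  The sensitivity harness refits
under prior overrides and/or a normal error family and reports the largest
movement in coefficient medians (overall and covariate-only — the
intercept/spline split is weakly identified, only their sum is) and in the
median predictive curve.

## Problem sizes and runtime

Desk-scale defaults keep every check on one CPU: parameter recovery uses
30 replicate cohorts of 300 women (~6 s per fit); chart calibration one
10,000-woman stratum (~2 min for the 8,000-woman fit); the full test
suite runs in roughly 10 minutes and `scripts/acceptance.py` in roughly
the same.  All randomness flows from explicit integer seeds; the
acceptance script derives every stage seed from its `--seed` argument.

## Known limitations

- The sampler is specialised to this model family; adding covariate–GA
  interactions or non-intercept random effects would require new update
  blocks.
- Smoothing is pluggable but only the cubic smoothing spline is shipped;
  chart values beyond the data boundary are linear extrapolations and
  should be displayed as such.
- The coverage verdict uses independence-based binomial intervals (see
  caveat above).
- Synthetic cohorts are generated under the fitted model's own assumptions;
  real-data adequacy (posterior predictive checks against a registry)
  is out of scope here.
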
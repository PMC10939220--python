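# Methods

This note records the model, the defaults, and the design choices made where
the method left genuine freedom — in the spirit of the methods documentation
of packages like statsmodels or msprime. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The mortality model

Two-year all-cause death is modelled by survey-weighted logistic regression
on fourteen terms: intercept; age − 20; male sex; decayed lifetime smoking
exposure (thousands of packs); f(BMI); log physical activity; diet score;
five chronic-disease indicators; and the products (age−20)×sex and
(age−20)×f(BMI). The coefficients maximize the weighted log-likelihood
(statsmodels IRLS); terms fixed a priori enter as an offset and are excluded
from inference. The design-based covariance is the stratified
with-replacement PSU Taylor linearization

V(β̂) = A⁻¹ B A⁻¹, A = Xᵀ diag(wμ(1−μ)) X, B = Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)(z_hj − z̄_h)ᵀ,

with z_hj the PSU total of the weighted score contributions — the same
estimator as R's `survey::svyglm`. Strata containing a single PSU raise an
error suggesting collapse; `single_psu="certainty"` instead lets them
contribute no between-PSU variance. Confidence intervals use the normal
quantile 1.959964 and are reported to 4 decimals.

**Fixed physical-activity coefficient.** The freely estimated activity effect
is implausibly strong (reverse causation: terminal illness suppresses
activity), so β₅ = −0.1000 per log MET-min/week is fixed from literature
meta-analyses and carries no standard error. The Wald/Holm testing family is
the twelve estimated non-intercept terms.

**BMI sign constraint.** The combined BMI coefficient c(a) = β₄ + β₁₃(a−20)
must be nonnegative for ages 20..A_max (default A_max = 80; with the
reference coefficients c(a) reaches 0 exactly at 80). If the unconstrained
optimum violates the constraint, the model is refit on the active boundary:
either β₁₃ = −β₄/(A_max−20) (substituted column), β₄ = 0 (dropped column), or
the vertex β₄ = β₁₃ = 0; among feasible candidates the one with the highest
weighted log-likelihood is kept, and covariances map through the
reparametrization Jacobian. Beyond A_max the combined coefficient is floored
at 0 when evaluating linear predictors, so abnormal BMI is never protective.

## Predictor engineering

- **Smoking:** x₃ = packs_lifetime · max(0, 1 − years_since_quit/25), in
  thousands of packs; current smokers use years_since_quit = 0. The exposure
  is exactly 0 from 25 years after cessation.
- **f(BMI):** the method requires a continuous U-shape that is constant on
  the normal range; the functional family and slopes are otherwise free. We
  use the simplest such shape — piecewise linear, 0 on [18.5, 25] kg/m²,
  slope 1 per kg/m² above 25 and slope 2 below 18.5 (underweight carries the
  steeper gradient) — both slopes configurable. Coefficient magnitudes are
  only interpretable jointly with this scale.
- **Physical activity:** ln(1 + MET-min/week). The unit offset is our
  zero-handling choice (41% of adults report none); it makes the transform
  finite, monotone and 0 at 0.
- **Winsorization** clips continuous inputs at the (unweighted) 1st/99th
  percentiles, numpy's linear-interpolation percentile convention. It is off
  by default for synthetic data (whose tails are controlled by construction)
  and available via `build_features(winsorize_continuous=True)`.
- **Imputation** is deterministic single imputation: sex × 10-year-band
  median (continuous) or mode (binary), falling back to the overall value for
  empty cells, with a per-variable report. Chosen for bit-reproducibility
  over multiple imputation; design variables and the outcome must be
  complete.

## Baseline profiles

Survey-weighted means (prevalences) of the engineered predictors x₃..x₁₁ plus
raw BMI and activity are computed per sex and single year of age (cells under
30 records fall back to their 5-year band) and smoothed over age with cubic
smoothing splines, penalty chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`), weighted by cell counts.
Smoothed prevalences are clamped to [0, 1]; outside the observed age range
(20–84 in the synthetic cohort) the endpoint value is carried flat rather
than extrapolating a cubic polynomial to age 110. Baselines are kept on the
engineered scale, and disease prevalences are part of the baseline: both are
required for the baseline-LE identity to hold when disease terms are in the
model.

## Personalization and life expectancy

For two-year steps from the current age: q₂ = 1 − (1−q_x)(1−q_{x+1});
odds' = q₂/(1−q₂) · exp(η_ind(a) − η_base(a)); q₂' = odds'/(1+odds'). The
age-dependent terms of both linear predictors (x₁, i12, and the combined BMI
coefficient) are evaluated at each table age, not frozen at the current age.

**Annual split.** The adjusted two-year probability is split back into two
annual probabilities by scaling both annual odds by a common factor t solving
(1+o_a t)(1+o_b t) = 1/(1−q₂′) — a quadratic with a unique positive root,
evaluated in a cancellation-safe form. When the adjustment is the identity,
t = 1 and the original annual probabilities return exactly; this is what
makes the baseline identity hold age by age (an equal-annual-survival split
would replace each q by the geometric-mean-survival complement and break it).
A dangling single year before the terminal age is adjusted at one-year
resolution; the terminal age ω keeps q = 1. Odd current ages simply start the
two-year stepping at the current age.

LE is the standard period life-table sum LE = Σ l_x (1 − q_x/2) with
fraction-of-year-lived a_x = 0.5 in every interval, so certain death within
the year yields LE = 0.5 and a constant hazard q yields (1−q)/q + 0.5.

## Projection of covariates

Population age curves are fitted per sex: a weighted least-squares quartic
polynomial for mean BMI, and a·exp(b·age)+c for mean activity (fitted to
per-age weighted means, which is robust to the zero-inflated individual
distribution). Individuals are carried as deviations from the curves —
additive for BMI (keeps extremes realistic), multiplicative with floor 0 for
activity (keeps it nonnegative); both strategies are selectable. Smoking
exposure decays for quitters and, by default, keeps accruing for current
smokers at their current rate (from `packs_per_month` if supplied, else
lifetime packs averaged since age 18); diet score is held constant.

Diseases are irreversible: diagnosed ones stay at 1, otherwise the expected
indicator evolves by the absorbing update p ← p + (1−p)·onset. The annual
population onset hazard is derived from the prevalence curve as
max(0, Δprev)/(1 − prev) — a prevalence-based stand-in chosen because no
incidence source is part of the inputs. Individual onset multiplies the
unexposed hazard (population hazard × (1 − PARF)) by the product of the
individual's relative risks, treated as independent and capped at 1. Using
the *expected* indicator inside the linear predictor is an approximation (the
model was fitted on 0/1 flags); it is accurate for small probabilities and
keeps LE deterministic. PARFs, prevalence curves and RR tables are
configuration (`perlife/data/disease_risk.yaml` ships synthetic illustrative
values); which exposure maps to which RR is deliberately config-driven, not
hard-coded.

## Validation

Bootstrap replicates resample PSUs with replacement within each stratum (as
many draws as the stratum has PSUs, so the expected multiplicity of each PSU
is one and weights are kept); drawn copies are relabeled as distinct PSUs so
the replicate preserves the design structure. Each replicate is refitted;
train metrics are computed on the replicate and test metrics on the original
data, with the Youden threshold recomputed on the replicate and carried to
the test evaluation (the threshold is part of the model under validation).
Optimism = mean(train − test); corrected = apparent − optimism; the 95%
uncertainty interval is the 2.5/97.5 percentile range of the per-replicate
corrected values. Non-converging replicates are logged and skipped. LE
uncertainty intervals recompute LE under each replicate's coefficients with
the baseline profile and life table held fixed — they propagate coefficient
uncertainty only, which understates total uncertainty; B defaults to 200.

## The synthetic-data generator

The generator emulates the statistical structure of a pooled national health
examination survey of adults aged 20–84 (open-ended top age intervals are
excluded; ages are uniform over 20–84):

- stratified two-stage design; weights lognormal around a per-stratum base
  (dispersion 0.5), normalized to the sample size — unequal-probability
  sampling without modelling oversampling rules;
- BMI lognormal (median ≈ 27.7 kg/m², σ_log 0.21) with a mild mid-life hump;
- leisure-time activity zero-inflated lognormal: 41% zeros at age 45, rising
  with age (logit slope 0.035/year), nonzero part median ≈ 1200 MET-min/week
  declining ~1%/year — reproducing a median near 250 with zero-inflation;
- smoking: 45% ever-smokers, half of them quit (exponential time since
  quitting, mean 12 y, truncated at age 18), pack-lifetimes lognormal
  (median ≈ 3 thousand packs, accumulating ~2%/year of age);
- diet score normal(2.1, 5);
- disease indicators from logistic-in-age prevalence curves calibrated to
  plausible adult prevalences (e.g. diabetes ≈ 9% overall), independent given
  age and sex; an optional Gaussian-copula correlation between the lifestyle
  factors is available but defaults to independence, since the joint
  dependence is not part of the documented inputs;
- the death indicator is Bernoulli from the reference logistic mechanism
  applied to the engineered predictors; with the reference intercept the
  weighted two-year death fraction comes out ≈ 2% (the acceptance script
  recomputes it).

The period life table generator uses a Gompertz–Makeham hazard
μ(x) = λ + a·e^{bx} with the closed-form annual probabilities and per-sex
defaults roughly matching recent US period mortality; the terminal age
(default 110) carries q = 1.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: questionnaire measurement error and self-report biases,
oversampling of subpopulations, correlation among lifestyle factors (under
the default), secular trends across survey cycles, and probabilistic
mortality linkage error. Tests demonstrate that the machinery is correct
under a known mechanism, not that the reference coefficients are unbiased for
any particular population.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to separate signal from Monte-Carlo
noise: coefficient recovery refits n = 200,000 cohorts over 20 seeds on a
100-PSU design (25 strata × 4 PSUs — the pooled multi-cycle survey structure;
few huge PSUs would both destabilize design-based SEs and blind the PSU
bootstrap to record-level overfitting); the null-signal optimism check uses
n = 20,000, B = 50 with a balanced outcome, where the corrected-AUC noise
(≈0.003) is well inside the 0.48–0.52 acceptance band — at a 2% event rate
the AUC's own sampling noise (≈0.016) would dominate the property being
tested; the life-expectancy oracle simulates 10⁶ lives. IRLS runs to
tolerance 1e-10 (max 200 iterations); separation is flagged when any
coefficient exceeds 50 in absolute value. The baseline identity holds to
~1e-14 years in double precision. All randomness flows through
`numpy.random.default_rng` seeds derived from a single root seed.

## Known limitations

- The f(BMI) scale (and therefore the BMI coefficient magnitudes) is a
  package convention; only the constraints stated by the method pin it down.
- The expected-disease-indicator approximation slightly misstates the odds
  adjustment when projected disease probabilities are large at old ages.
- Percentile lifestyle profiles rank BMI by its penalty f(BMI) and map the
  selected penalty back to the overweight branch (the dominant side);
  underweight profiles are not generated.
- LE uncertainty intervals omit life-table and baseline-profile uncertainty.
- The prevalence-derived onset hazard assumes negligible differential
  mortality by disease status within a year.
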
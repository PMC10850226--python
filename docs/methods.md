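# Methods

## Estimands and models

The package estimates natural direct and indirect effects of a
continuous exposure (age, in years) on a binary 90-day outcome through
a continuous mediator (the deficit-accumulation frailty index), under
the usual identification assumptions of regression-based causal
mediation: no unmeasured exposure–outcome, mediator–outcome or
exposure–mediator confounding given the covariates, and no
mediator–outcome confounder affected by the exposure.  The covariate
set (sex, race, admission NIHSS, smoking status) follows the
disjunctive-cause idea — adjust for causes of the exposure or of the
outcome; comorbidities are deliberately *not* covariates because they
are constituents of the mediator itself.

The structural models are a linear regression of the mediator on
exposure and covariates (residual variance σ², estimated as
RSS/(n − p)) and a logistic regression of the outcome on exposure,
mediator, optionally their product, and covariates (maximum likelihood
via Newton scoring; covariance from the inverse observed information).
The closed-form log odds-ratio expressions for NDE/NIE (see README) are
exact for the linear/logistic pair only in the rare-outcome limit,
where odds ratios approximate risk ratios.  The identity
log TE = log NDE + log NIE holds *by construction* of the estimator, at
machine precision, and is asserted in the tests.

### Where the approximation bites

The rare-outcome error grows with outcome prevalence and with the
mediated signal θ₂σ.  The test suite carries an approximation-error
fixture: with a strongly mediated effect (β₁ = 0.02, σ = 0.12) the
closed form agrees with the counterfactual Monte-Carlo truth at 2%
prevalence but overshoots it by ≈ 5% of the effect (≫ 3 MC SEs) at 40%
prevalence.  Because stroke cohorts have common outcomes (≈ 47%
composite, ≈ 18.5% mortality), the estimator emits a warning whenever
prevalence exceeds 10% rather than silently proceeding; estimates are
then interpretable as OR-scale summaries but not as risk-ratio-like
natural effects.

## Frailty index

Each of ≥ 30 binary deficit items scores 1 when present, 0 when absent;
the index is present/assessed.  Missing items are removed from the
denominator (standard deficit-accumulation practice); when fewer than
80% of items were assessed (`min_assessed_fraction`, configurable) the
index is treated as missing and the record falls to the complete-case
filter.  Graded items must be dichotomised at schema level — scoring is
strictly 0/1.  The packaged 31-item schema (comorbidities plus baseline
disability flags) exists so the pipeline is runnable end to end; it is
a generic stand-in, and real analyses should supply their instrument as
a YAML/JSON schema file.  The index is used downstream only as a
continuous variable; no frailty cut-points exist anywhere in the
pipeline.

## Uncertainty

Delta-method SEs propagate the analytic gradients of the log-OR
expressions through the block-diagonal coefficient covariance
(mediator-model block, outcome-model block).  Two simplifications
follow the standard implementation of this estimator family: σ² is
treated as fixed, and the two blocks as independent.  The participant-
level bootstrap (`bootstrap_mediation`, percentile intervals, default
B = 2000, resamples that separate or fail to converge are dropped and
counted, > 10% dropped is an error) exists precisely to quantify what
those simplifications cost; the acceptance suite checks that delta and
bootstrap endpoints agree within 10% of the interval width on a
synthetic cohort with adequate events (n = 3000 at 5% prevalence —
with ~60 events the bootstrap distribution is visibly skewed and no
normal-theory interval should be expected to match it).

The proportion mediated PM = OR_NDE(OR_NIE − 1)/(OR_NDE·OR_NIE − 1) is
computed on the OR scale, never as a naive ratio of log-ORs.  Its CI
comes from the delta method in (log NDE, log NIE) using their joint
2×2 covariance; the reported interval is truncated to [0, 1] while the
raw interval is kept in the machine output.  PM is undefined when the
total-effect OR is 1 (an explicit error).

## Exposure contrast and conditioning

Defaults: a* = sample mean age, a = a* + 1 year (so odds ratios are per
1-year increment; age is never rescaled), covariate conditioning values
c = sample means.  Both are configurable and recorded in every report.
Without the interaction term the estimates are invariant to c; with it,
c matters and the default is flagged in the decisions log.

## Interaction screening

`test_interaction` fits the outcome model with and without the age ×
frailty product term and reports the Wald z for θ₃, the LR test of the
nested pair, and the induced change in log NDE/log NIE.  Detectability
of an interaction in this design is intrinsically poor because A·M is
nearly collinear with M (age varies ± 13 years around ~68); a
detectable scenario must keep the frailty slope at the mean age fixed
while tilting it with age (`strong_interaction_params` offsets
θ₂ by −θ₃·mean age), otherwise the product term saturates the
probabilities and power collapses at any sample size.

## GLM details

Newton scoring with tolerance 1e-8 on the coefficient change, at most
100 iterations, no penalisation — separation is an error, not a
fallback.  Separation is flagged when fitted probabilities are pinned
within 1e-6 of 0/1 *and* some coefficient spans more than ~30 logits
per SD of its column (a scale-aware divergence criterion; raw-scale
thresholds misfire on steep-but-finite effects such as ~70 per FI unit
≈ 3 per FI SD), or when the information matrix goes singular during
iteration on a design already verified full-rank.  VIFs are 1/(1 − R²)
from regressing each column on the others; exact collinearity reports
infinity, and any VIF above 3 triggers a warning.

## Synthetic cohorts

The generator reproduces marginal structure, not joint structure:
age ~ truncated normal (67.7, 13.1², floor 19); sex/race/smoking
independent categorical draws (0.565 male, 0.89 white,
0.517/0.192/0.291 never/former/current); NIHSS rounded lognormal
(log-mean ln 12, log-SD 0.7, clipped to [0, 42]) giving median 12 and
IQR ≈ 7–19.  The mediator is either Gaussian around its linear
predictor (β₁ = 0.002 FI units/year, σ = 0.045, clipped to [0, 1] with
the clip rate warned above 5%) or, in `deficit_level` mode, 31
Bernoulli items whose common age slope on the logit scale is calibrated
so the induced FI–age slope equals β₁ (item prevalences 0.01–0.19,
mean 0.10).  Outcomes are Bernoulli from the logistic truth with
θ₁ = ln 1.02/year and θ₂ = 5 (so OR_NIE ≈ 1.01/year and PM ≈ one
third — an illustrative echo of the motivating effect scale, not a
reproduction of any cohort).  Scenario intercepts θ₀ are solved once by
deterministic large-n root-finding against the scenario's prevalence
target (46.9% composite, 18.5% mortality, 2% for the rare-outcome
validation regime); mRS values are then assigned consistently with the
simulated dichotomy, with the composite scenario drawing death for
54/137 of poor outcomes so a single cohort matches the composite and
mortality margins simultaneously.

What passing tests do **not** show about real data: covariates here are
independent, the FI is homoscedastic and symmetric around its linear
predictor, and outcomes follow the logistic model exactly.  Real
cohorts violate all three; the validation demonstrates estimator
correctness under its own assumptions, not robustness to their failure.

## Validation experiments (sizes and why)

* Oracle: `true_effects` draws each counterfactual arm independently
  (plain Monte-Carlo, so its SEs are the honest yardstick for
  formula-vs-truth comparisons), n_mc = 10⁶ for equivalence checks and
  10⁷ when serving as the reference for recovery experiments, where its
  own error must be negligible against the bias tolerance.
* Recovery: 500 replicates at n = 5000 in the 2%-prevalence regime;
  bias of log NDE/log NIE within 3 MC SEs.  Coverage: 1000 replicates
  at n = 2000; 95% delta CIs for log NIE must cover in [93%, 97%].
* Interaction type-I error: 1000 null replicates at n = 2000, 5%
  prevalence; rejection rate within the 3-SE binomial band around 5%.
* These sizes keep the whole suite around a minute while leaving every
  tolerance comfortably dominated by the statistical signal being
  checked.

## Degenerate inputs and tie-breaks

Quantiles everywhere use linear interpolation (type 7).  Constant
vectors route to the nonnormal summary (Shapiro–Wilk is undefined);
normality is Shapiro–Wilk at α = 0.05 per group.  The chi-square test
carries no continuity correction; Fisher's exact test is two-sided by
summing hypergeometric probabilities ≤ the observed table's, and is
restricted to 2×2 (larger sparse tables must be collapsed — an explicit
error).  The Wilcoxon rank-sum test uses the tie-corrected normal
approximation without continuity correction, so identical groups give
p = 1 exactly.  Records are dropped only by the complete-case filter,
which attributes each exclusion to the first missing variable in the
declared order; `died_90d` is derived from mRS = 6 when absent and a
conflict between the two is a validation error.

## Known limitations

Single mediator, binary outcomes only; no survival models, no ordinal
mRS analysis, no multiple imputation (by design — complete case), no
sensitivity analysis for unmeasured confounding.  The delta method
ignores uncertainty in σ²; use the bootstrap when that matters.
Proportion mediated is unstable when the total effect is near null —
expect wide, possibly truncated intervals exactly as in underpowered
mortality analyses.
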
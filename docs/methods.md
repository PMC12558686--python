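# Methods

This note documents the statistical machinery in `msmediation`, the
synthetic cohort it is validated against, and the design decisions made
where the methodology left genuine choices.

## The estimation problem

A three-wave panel observes, for each subject, time-invariant covariates
(sex, ethnicity, education, housing), time-varying covariates L_t (age,
mobility difficulty, four chronic conditions, a 0–60 social-support
score), a binary exposure X_t (chewing disability, waves 1–2), a binary
mediator M_t (loneliness, waves 1–2), monotone censoring C_t, and a
terminal outcome Y at wave 3 (clinically significant depressive
symptoms, CSDS: 11-item CES-D ≥ 7). The estimands are the marginal
("population-averaged") risk ratios comparing always-exposed to
never-exposed regimes — the total effect, and a direct effect with the
mediator path held fixed — plus the share of the total effect that runs
through the mediator.

Time-varying confounders lie on the causal pathway (earlier exposure
worsens later mobility and support, which drive later exposure, dropout
and outcome), so conditioning on them in an outcome regression blocks
part of the effect while failing to close the backdoor paths. Marginal
structural models avoid this by weighting: each subject is reweighted by
the inverse probability of the exposure, mediator and censoring history
they actually had, stabilized by history-only numerators.

## Weight construction

Six logistic model pairs are fitted, one numerator and one denominator
per exposure/mediator wave and per censoring wave. Wave-1 numerators
condition on nothing beyond available history (there is no wave-0
state): the X₁ numerator is the marginal exposure prevalence and the M₁
numerator conditions on X₁ only. Censoring numerators are marginal
retention probabilities, following the SW^C formula's
P(C_t | C_{t-1}); censoring denominators add exposure and mediator
history to L, because dropout that depends on exposure history cannot
otherwise be corrected — the covariate vector "L_t" in the weight
formulas is read as the full measured history. All links are logistic
with main effects; models are fitted only on subjects at risk
(uncensored entering the wave), and fits that separate perfectly or
fail to converge raise rather than return boundary probabilities. A
denominator probability of zero for an observed state raises a
positivity error; it is never clipped silently.

Components multiply into `SW_total` over the analysis set (subjects
observed through wave 3). By default both outcome models use the single
combined exposure × mediator × censoring weight, mirroring the standard
applied practice for this design; exposure × censoring weighting for
the total-effect model is available (`include_mediator=False`).
Combined weights are truncated at the 95th empirical percentile
(linear-interpolation definition; upper-only by default, symmetric
optional), and diagnostics report mean/SD/1st/95th/99th percentiles
before and after truncation plus, per model and wave, the fraction of
denominator predicted probabilities outside (0.05, 0.95) — the
positivity screen — with an alarm above 5%.

Truncation of the *combined* weight (rather than per-component) is one
reading of the usual "truncated at the 95th percentile" prescription;
it is flagged in the diagnostics metadata.

## Outcome models and decomposition

With one terminal binary outcome per subject, the analysis rows carry
`cum_x`, `cum_m` ∈ {0, ½, 1} — the mean of the two wave indicators, so
that a single coefficient contrasts always- with never-exposed (sum
coding {0,1,2} is available). The total model regresses Y on `cum_x`,
the direct model adds `cum_m`; both are weighted Poisson fits with log
link and an HC0 sandwich covariance (weights enter the score, hence
squared in the meat — the standard IPW "robust Poisson" for risk
ratios). No small-sample correction is applied by default, and no
within-subject clustering is needed because each subject contributes one
outcome row.

The mediated share is decomposed on the excess-relative-risk scale:
`proportion_direct = (RR_direct − 1)/(RR_total − 1) × 100`, and
`proportion_mediated = 100 − proportion_direct` (computed as the exact
complement so closure holds to the last bit). When RR_total ≤ 1 the
proportions are reported as undefined rather than as NaN. The
"mediator RR" reported is exp(β2) from the direct model. E-values use
RR* + √(RR*(RR*−1)) with RR* = max(RR, 1/RR); confidence-limit E-values
use the limit nearer the null and collapse to 1 when the interval
crosses 1.

The continuous-score sensitivity analysis replaces the Poisson fits
with weighted least squares (identity link, HC0) on the raw CES-D
score, with the TILS score as mediator, and converts mean differences
to approximate risk ratios via exp(0.91·MD/SD). The reference SD
defaults to the outcome-score SD among never-exposed analysis subjects,
since no external reference is available. In continuous mode no
baseline-outcome exclusion is applied.

## Missing data

Chained-equations imputation sweeps columns in causal order (covariates
→ exposure → mediator → outcome), drawing binary columns from fitted
logistic probabilities and score columns by predictive mean matching
(five nearest-prediction donors). A wave-t column is imputed among
subjects still observed at wave t, using predictors measured no later
than wave t: with monotone dropout, later-wave predictors do not exist
for the censored, so the textbook "use everything including the
outcome" prescription is applied within the constraint of the monotone
pattern. Ten datasets and ten sweeps by default; a diverging sub-model
falls back to a draw from the observed margin with a logged warning;
observed cells are never altered. Rubin's rules pool estimates with
total variance W̄ + (1 + 1/m)B and the classic Rubin degrees of
freedom; ratio effects are pooled on the log scale.

MNAR bounds complete every wave-3-censored subject's outcome as
negative (best case) or positive (worst case). Subjects censored before
wave 2 have their wave-2 exposure/mediator/covariates carried forward
from wave 1 — an explicit assumption, configurable in principle to
MI-based completion — and the re-analysis keeps exposure and mediator
weights but drops censoring weights, since no one is censored after
completion. Uniform best/worst completions bound each arm's *risk*, not
the risk *ratio*; bracketing of the censoring-weighted estimate by the
two bounds is therefore a property of the dropout regime, not a
theorem. The bracketing test uses a moderate, outcome-dependent dropout
regime (dropout driven by the outcome's risk factors, retention mildly
favoring the exposed) — the regime consistent with the published
pattern in which the best-case bound exceeded the primary estimate and
the worst-case fell below it. Under very heavy attrition both bounds
compress toward the null and can fall on the same side of the weighted
estimate.

## Bootstrap

BCa intervals resample whole subjects with replacement and re-run the
entire estimation (weight models refitted inside every replicate;
truncation re-applied). The bias correction z₀ uses the fraction of
replicates below the point estimate with ties counted half; the
acceleration comes from the jackknife skewness; endpoints are
linear-interpolation percentiles of the replicate distribution at the
BCa-adjusted levels. Replicates whose statistic raises a package error
are dropped and counted; >5% failures warns, >50% aborts. The default
B is 5,000 for release runs; tests use a few hundred to a few thousand.
The jackknife makes BCa cost n extra statistic evaluations, so for
expensive full-pipeline statistics the robust-Wald interval is the
pragmatic default and BCa the audit option.

## The synthetic cohort and its oracle

The generator draws wave-1 covariates at published baseline margins of
a large urban cohort of adults 60+ (53.5% female, 16.8% exposure
prevalence, 41.7% mediator prevalence, age 70.4 ± 7.1, support
30.2 ± 12.6, and so on), then propagates logistic structural equations
wave by wave in the order L_t → X_t → M_t → C_{t+1}, with Y last.
Exposure–confounder feedback (X₁ worsens wave-2 mobility and support)
and exposure-dependent retention produce exactly the time-varying
confounding and informative dropout the weights exist to fix. Age
advances deterministically (+2, +3.5 years, the survey's calendar);
chronic conditions are absorbing with small incidence; scores are
rounded, range-clipped latent Gaussians so binary and continuous
analyses run off one cohort. Retention defaults (64.5% to wave 2, 52%
of those to wave 3) mirror the source survey's attrition, so a
5,000-subject cohort yields ≈1,300 analyzable subjects — deliberately
the scale of the original analysis sample.

Structural intercepts are calibrated per cohort by solving for the
value that makes the realized margin hit its target (wave-1 exposure
and mediator prevalences, wave-2 drifted targets, retention rates, and
outcome prevalence among completers), so margins stay on target when
structural coefficients change. One deviation from the all-logistic
design: the binary outcome follows a log-risk (exponential) structural
model, risk capped at 0.98. A logistic outcome makes the marginal
dose-response concave on the log-risk scale, so the pooled log-linear
MSM's exp(β1) differs from the true always-vs-never contrast by a
functional-form gap (≈+0.04 at the default effect sizes) even with
perfect weights; with a log-risk outcome the analysis model is
correctly specified for the generated population and parameter-recovery
tests isolate the weighting machinery, which is what they exist to
check. X, M and C remain logistic, so the weight models stay
nontrivially specified.

Default effect sizes (x_y = 0.11 per exposed wave, m_y = 0.30 per
lonely wave, x_m = 0.5) place the oracle total risk ratio near 1.5 with
roughly a fifth to a quarter of the excess risk mediated — the regime
reported for this design. The oracle propagates the same equations
under do(X₁=X₂=x) with censoring removed, using common random numbers,
and computes risks as means of the structural outcome probabilities
(not realized draws), which removes one layer of Monte-Carlo noise; the
direct contrast holds the mediator path at its value under
never-exposure (a randomized-interventional analogue — the estimand is
chosen here since the two-model MSM comparison does not itself name
one). Because the analysis screens out baseline-positive subjects, the
oracle by default conditions on the same event (natural baseline
CES-D < 7), keeping estimand and estimator aligned. Monte-Carlo
standard errors shrink as 1/√n_mc.

What the generator does *not* emulate: survey weights and household
sampling, interviewer effects, item-level questionnaire structure,
measurement error in the scores, and non-monotone (intermittent)
response patterns. Passing tests therefore demonstrate correctness of
the estimation machinery under a data-generating process faithful to
the design's causal structure — not robustness to every failure mode of
real survey data.

## Numerical and scale choices

* Percentiles everywhere use linear interpolation.
* Wald intervals use z = 1.96 on the link scale, exponentiated for
  ratios; Rubin pooling switches to t quantiles with the Rubin df.
* Weighted fits require strictly positive finite weights; constant
  outcomes raise degenerate-fit errors instead of returning NaN.
* Eligibility, coding, and weight estimation are deterministic; every
  stochastic step (generation, imputation, bootstrap) takes an explicit
  integer seed, and the pipeline echoes all resolved seeds into its
  report.
* Test problem sizes (cohorts of 2,000–5,000, 200 replicates for
  calibration studies, B ≤ 2,000 bootstrap replicates) were chosen so
  the full suite exercises every claim at the scale of the original
  design while remaining a desk-scale computation.

## Known limitations

* The mediation decomposition is the two-model excess-RR comparison;
  natural direct/indirect effects via the mediational g-formula are out
  of scope.
* Weight models are main-effects logistic regressions; no
  machine-learning weight estimation.
* The robust-Wald and BCa intervals ignore the uncertainty from weight
  *model selection* (they do account for weight re-estimation inside
  the bootstrap).
* MNAR completion bounds risks, not risk ratios (see above).
* With attrition as heavy as the defaults, single-cohort estimates at
  n = 5,000 are noisy (robust SE on the log-RR ≈ 0.2); replicate
  averages, not single draws, are the calibration evidence.
* The point estimator carries small, quantifiable finite-sample biases
  on the risk-ratio scale that users of replicate averages should know
  about. At the default conditions: 95th-percentile truncation pulls
  the estimate ≈ +0.02 toward the unweighted (confounded) value — the
  usual variance-for-bias trade; using the single combined weight for
  the total-effect model (rather than exposure × censoring only) shifts
  its estimand by ≈ +0.01; and because the estimate is approximately
  log-normal, its arithmetic mean across replicates exceeds the true RR
  by a factor ≈ exp(SE²/2) — ≈ +0.04 at the default effective sample
  size. The weighting itself is unbiased: at n = 150,000 the saturated
  weighted always-vs-never contrast matches the oracle to three
  decimals.
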
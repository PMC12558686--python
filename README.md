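# msmediation

Longitudinal causal mediation analysis with marginal structural models
(MSMs) fitted by stabilized inverse-probability weighting.

The package targets a common epidemiological design: a three-wave cohort
of older adults with a time-varying binary exposure (chewing disability,
dichotomized from an ordinal food-toughness scale), a time-varying binary
mediator (loneliness, TILS ≥ 1), informative monotone dropout, and a
terminal binary outcome (clinically significant depressive symptoms,
CES-D ≥ 7, at wave 3). Because time-varying confounders (mobility,
social support, chronic disease) are themselves affected by earlier
exposure, ordinary regression adjustment is biased; the package instead
reweights subjects by stabilized inverse-probability weights

```
SW_t^X = P(X_t | X_{t-1}) / P(X_t | X_{t-1}, L_t)
SW_t^M = P(M_t | X_t, M_{t-1}) / P(M_t | X_t, M_{t-1}, L_t)
SW_t^C = P(C_t | C_{t-1}) / P(C_t | C_{t-1}, L_t)
SW_total = (∏_t SW_t^X) (∏_t SW_t^M) (∏_t SW_t^C)
```

and fits two weighted pooled Poisson models with a log link and robust
(sandwich) standard errors:

```
total:   log P(Y=1 | x̄)      = β0 + β1·cum(x̄)
direct:  log P(Y=1 | x̄, m̄)  = β0 + β1·cum(x̄) + β2·cum(m̄)
```

`cum(·)` averages the two wave indicators, so `exp(β1)` is the
always-vs-never-exposed risk ratio. The mediated share of the total
effect is decomposed on the excess-relative-risk scale,
`proportion_direct = (RR_direct − 1)/(RR_total − 1)`, with
`proportion_mediated` its complement to 100%. Around this core the
package provides E-values for unmeasured confounding, chained-equations
multiple imputation with Rubin's-rules pooling, BCa bootstrap confidence
intervals over the entire re-estimation pipeline, deterministic MNAR
best/worst-case bounds for dropouts, weight-distribution and positivity
diagnostics with 95th-percentile truncation, and a continuous-score
sensitivity analysis (weighted least squares, with mean differences
converted to approximate risk ratios).

Since cohort data of this kind are typically access-restricted, the
package ships a first-class synthetic cohort generator calibrated to the
published baseline margins of such a survey, with exposure–confounder
feedback, informative monotone dropout, and a potential-outcome oracle
(`true_effects`) that computes the ground-truth marginal contrasts the
MSMs target — so the whole pipeline is testable end to end.

## Worked example

```python
import msmediation as mm

params = mm.default_params(n_subjects=5000, seed=42)
cohort = mm.generate_cohort(params)          # three-wave synthetic cohort
truth  = mm.true_effects(params, n_mc=300_000, seed=9)
result = mm.analyze_cohort(cohort)           # eligibility -> weights -> MSMs

s = result["summary"]
print(f"oracle total RR        {truth.true_total_rr:.3f}")
print(f"estimated total RR     {s.total_rr:.3f}")
print(f"estimated direct RR    {s.direct_rr:.3f}")
print(f"proportion mediated    {s.proportion_mediated:.1f}%")
print(f"E-value (total)        {s.evalues['total'].evalue_point:.2f}")
```

Output:

```
oracle total RR        1.514
estimated total RR     1.329
estimated direct RR    1.244
proportion mediated    26.0%
E-value (total)        1.99
```

The oracle says the truth in this simulated population is a 1.51-fold
risk; the weighted pipeline on this one 5,000-subject cohort (about
1,300 subjects surviving eligibility and follow-up) estimates 1.33 with
a direct effect of 1.24 — a single cohort at this effective size is
noisy, which is why calibration (bias, attenuation ordering, interval
coverage) is assessed over hundreds of replicates in
`tests/test_acceptance.py` rather than on any single draw. About a
quarter of this cohort's excess risk runs through loneliness, and an
unmeasured confounder would need risk ratios of about 2.0 with both
exposure and outcome to explain the total effect away.

A command-line interface wraps the same machinery:

```sh
msmediation simulate --n 5000 --seed 42 --out cohort.csv
msmediation run --cohort cohort.csv --out results/ --variant primary --variant continuous
msmediation weights --cohort cohort.csv --out weights.csv
msmediation report --report results/report.json
```

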
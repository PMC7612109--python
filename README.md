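# narfcs-sa

Sensitivity analysis for incomplete repeated binary outcomes in two-arm
trials, built around not-at-random fully conditional specification
(NARFCS) multiple imputation, expert elicitation of priors on nonresponder
behavior, and highest-density credible regions.

## The problem

Trials with self-reported binary outcomes — the motivating case is
smoking-cessation trials with abstinence measured at two follow-up times —
routinely lose 15–30% of outcomes to nonresponse. Analyses then rest on an
untestable assumption: missing at random (MAR), or the field's blunt
alternative of setting every missing outcome to smoking. Neither can be
verified, so the honest question is *how far the data may depart from MAR
before the trial's conclusion changes, and whether experts consider such
departures plausible*.

This package implements that workflow end to end:

1. **Imputation.** Missing outcomes `Y_1, Y_2 ∈ {0, 1}` are multiply
   imputed per arm by chained logistic models. Under MAR (FCS) each
   outcome is regressed on the other:
   `logit Pr(Y_j = 1 | Y_k) = α_jz + β_jz Y_k`. Under MNAR (NARFCS) the
   models gain the missingness indicators:
   `logit Pr(Y_j = 1 | Y_k, M_j, M_k) = α̃_jz + β̃_jz Y_k + γ_jz M_k + δ_jz M_j`,
   where the offsets `δ_jz` — one per arm `z` and time `j` — are
   *sensitivity parameters*: fixed log-odds differences between
   nonresponders and responders that the data cannot identify.
2. **Analysis and pooling.** Each completed copy is analysed with the
   unadjusted model `logit Pr(Y_j = 1 | Z) = α_j + β_j Z`; estimates are
   pooled by Rubin's rules with Barnard–Rubin degrees of freedom.
3. **Elicitation.** Experts answer a short questionnaire (mode + certainty
   sliders defining truncated-normal curves on 0–100%, plus one
   updated-mode question that pins the between-arm correlation of their
   views). Responses become bivariate truncated-normal priors on the
   nonresponder quit-rate pair `(π_C^NR, π_E^NR)`.
4. **Credible regions.** 50%/90% highest-density regions (HDRs) per expert
   and for the linear opinion pool (an equal-weight mixture, sampled and
   estimated by kernel density estimation).
5. **Sensitivity analysis.** A grid of `(δ_1C, δ_1E)` over [−4, 4] in
   steps of 0.5 (289 sets, with second-time offsets tied to the first,
   `δ_2z = δ_1z`) is imputed and analysed; pooled odds ratios and
   p-values are mapped onto the interpretable `(π_C^NR, π_E^NR)` plane and
   overlaid with the elicited credible regions. A conclusion is
   *insensitive* when the credible regions stay inside the `p > 0.05`
   territory.

Because trial microdata of the motivating study are not shared, the
package ships a synthetic-trial generator with a known MNAR selection
mechanism, calibrated to the published summary rates, so every stage is
testable against ground truth.

## Worked example

```python
import numpy as np
import narfcs_sa as ns

data, truth = ns.generate_trial(ns.mnar_config(seed=7))

ms = ns.missing_equals_smoking(data)
print(np.exp(ns.fit_effect_model(ms, 1).beta))          # 1.070

imps = ns.fcs_impute(data, ns.ImputationConfig(m=20, n_cycles=10, seed=1))
pooled = ns.pool_effects(imps, 1)
print(pooled.odds_ratio, pooled.ci_low, pooled.ci_high)  # 0.996 0.713 1.392

grid = ns.build_sp_grid(ns.SPGridConfig(delta_range=(-2, 2), step=1.0))
res = ns.run_sensitivity(data, grid, ns.ImputationConfig(m=5, n_cycles=5, seed=2))
print(ns.between_time_correlation(res, "C")[0])          # 0.979
```

The missing=smoking odds ratio at the first follow-up is 1.070 and the
MAR-pooled odds ratio 0.996 (95% CI 0.713–1.392): with ~10% of first
follow-up outcomes missing, neither analysis finds an effect. The 25-row
sensitivity grid re-imputes the data at each offset pair; the between-time
correlation of the nonresponder quit-rate estimates (0.979 here) confirms
that tying the second-time offsets to the first yields the strongly
positively correlated estimates the linkage assumes. On this dataset the
generator's truth sidecar reports true nonresponder quit rates of 22.6%
(control) and 10.0% (experimental), so grid rows near those values
recover the complete-data effect.

A command-line surface mirrors the workflow: `narfcs-sa simulate`,
`narfcs-sa elicit build-priors`, `narfcs-sa hdr pooled`,
`narfcs-sa impute --method {mar|narfcs|missing-smoking}`,
`narfcs-sa sa run`, `narfcs-sa sa report`. Every subcommand writes a
manifest (settings + seed + version) next to its outputs.

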
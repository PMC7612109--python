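# Methods

## Data model and coding

Participants carry an arm indicator `Z` (0 = control, 1 =
experimental/intervention) and two binary outcomes `Y_1`, `Y_2`
(1 = abstinent/quit, 0 = smoking) at two follow-up times. Missingness
indicators `M_j` equal 1 exactly when `Y_j` is unobserved and are always
derived from the data, never stored. Nonmonotone patterns (missing at the
first time, observed at the second) are permitted and, in fact, required
for the MNAR machinery: the `γ` coefficients on the other outcome's
missingness indicator are estimable only because such patterns occur.

## Synthetic trial generator

The generator emulates a two-arm smoking-cessation trial. Within each arm
the joint distribution of `(Y_1, Y_2)` is a 2×2 table parameterized by two
marginal quit probabilities and an odds ratio; the `Y_1 Y_2` cell
probability solves the standard quadratic, with the Fréchet bounds
checked explicitly. Each outcome is then masked independently with
probability `expit(a_jz + b_jz · Y_j)`; any `b ≠ 0` makes the mechanism
MNAR by construction, and the pre-mask copy plus the realized mask give
the exact nonresponder quit rates `π^NR` (percent, integer arithmetic;
undefined — NaN, never 0 — when an arm/time has no masked participants).

Defaults for the trial-like configuration follow the published summary of
the motivating study: arm sizes 303/299; responder quit rates 50%/53% at
the first follow-up; missingness 18.2%/14% (first) and 21.5%/23.4%
(second). Second-follow-up quit rates are not published; we calibrate
them to 38%/40.3% among responders so the missing=smoking odds ratio at
the second follow-up lands near the published estimate. The within-arm
`Y_1`–`Y_2` odds ratio is likewise unpublished; the default of 6 reflects
the strong persistence of abstinence between 8 weeks and 6 months and is
an explicit config knob. The generator reproduces study *structure*
(sizes, rates, nonmonotone missingness), not covariates, recruitment
clustering, or reporting bias — passing tests demonstrate correctness of
the machinery under this structure, not fidelity to any real trial.

## Imputation engine

One chained-equations engine serves MAR (FCS) and MNAR (NARFCS), run
separately per arm. Missing cells initialize from draws of the within-arm
observed marginal (the conventional chained-equations start). Each of the
`n_cycles` sweeps refits, for each outcome in turn, a logistic model on
the rows where that outcome is observed — regressors: the other outcome's
current values, plus (NARFCS only) the other outcome's missingness
indicator — then draws a coefficient vector from the asymptotic normal
posterior (mean = MLE, covariance = inverse observed information) and
imputes missing values as Bernoulli with
`logit p = linear predictor + δ_jz`. The offset applies only to imputed
rows (their own `M_j` is 1) and therefore can never leak into the fitted
coefficients, whose fit rows all have `M_j = 0`. Defaults `m = 20` copies
and 10 cycles; results are reported as stable across `m` in the 10–50
range, and the tests use `m = 5` with coarser grids for speed.

Fitting is Newton–Raphson IRLS. Separation or non-convergence (detected
by coefficient blow-up past ±35 on the logit scale or a singular
information matrix) triggers a warning and a refit with a small ridge
penalty (default 1e-4, configurable) — at extreme offsets, small arms
make separation a routine event rather than an error. Coefficients are
refit and redrawn every cycle (standard chained-equations behavior; a
per-imputation draw would be the alternative). A test hook
(`posterior_draws=False`) pins the draw at the MLE so distributional
properties of single imputations can be checked exactly.

Seeding contract: a master seed spawns an independent substream per
(imputation index, cycle, variable), so results do not depend on
evaluation order; in the sensitivity grid each row's seed is a pure
function of the master seed and the row's δ values, so any subset of rows
recomputed in isolation reproduces the full run bit for bit.

## Analysis models and pooling

The per-copy analysis is the unadjusted logistic regression of each
outcome on the arm. On completed data this is saturated on the 2×2
arm-by-outcome table, so the fit is closed-form: `β` is the log
cross-product ratio and its SE the root of the summed reciprocal cell
counts (verified against an iterative logistic fit in the tests). An
empty cell flags the estimate non-finite rather than raising. Pooling
uses Rubin's rules — `T = W + (1 + 1/m)B` — with Barnard–Rubin
small-sample degrees of freedom (complete-data df `n − 2`), t-based
confidence intervals and two-sided p-values; the exact df convention of
any particular software run is a documented tolerance source. `π^NR` per
arm/time is the average over copies of the imputed quit proportion among
originally-missing participants — in [0, 100] by construction, NaN when
there is nobody to impute.

## Elicitation

Marginal priors are truncated normals on 0–100%: the elicited mode is the
underlying normal's mean and the certainty score maps linearly to its sd
(`sd = sd_max − (score/100)(sd_max − sd_min)`, defaults 30 down to 1
percentage point — the mapping is a front-end convention, so both
endpoints are configuration). Using the elicited mode/sd for the
*underlying* normal matches the curve the expert actually sees;
truncation then reshapes the realized marginal slightly (moment-matching
the truncated distribution would be the alternative and is deliberately
not the default).

The between-arm correlation comes from the updated-mode question via the
conditional-mean shift of a bivariate normal:
`ρ = (updated_mode − mode_C) / (z_0.75 · sd_C)` with `z_0.75 ≈ 0.6745`.
This makes the two anchor answers exact — no shift ⇒ ρ = 0, marking the
displayed upper quartile ⇒ ρ = 1 — and is clipped to ±0.99 so the
degenerate case still admits an HDR. The correlation is elicited once and
reused at the second follow-up time (an override exists). Bivariate
priors are the correlated normal truncated to [0, 100]²; sampling is by
rejection, with an explicit diagnostic error if the acceptance rate
collapses.

## Highest-density regions and pooling

HDRs use the density-quantile construction: estimate the density, then
take the threshold for coverage `1 − α` as the α-quantile of density
values at the sample points; the region is the superlevel set, so regions
at increasing coverage nest by construction and a bimodal pool may
legitimately produce disconnected 50% regions. The density estimator is a
binned 2-D Gaussian KDE (histogram + Gaussian blur) with per-axis
normal-reference bandwidth `σ_j n^{−1/6}` and a configurable multiplier;
binning keeps construction O(grid) so the 10⁵-sample default (and the
millions of samples print-quality contours want) stay cheap. Contour
polylines are clipped to [0, 100]²; the KDE itself is not boundary
corrected, so regions hugging 0% carry the usual edge bias — a caveat,
not a correction we apply. The opinion pool is the mixture of expert
priors, realized by concatenating per-expert samples; unequal weights
change the per-expert sample counts (largest-remainder rounding).

## Sensitivity analysis

The grid varies `(δ_1C, δ_1E)` over [−4, 4] by 0.5 (17² = 289 sets) and
ties later times to the first through linkage constants,
`δ_1z = c · δ_tz`, i.e. `δ_tz = δ_1z / c`, defaulting to equality. This
keeps the analysis two-dimensional at the cost of fixing the between-time
correlation of the `π^NR` estimates; the `between_time_correlation`
diagnostic computes that correlation across grid rows so the analyst can
judge (and, via the constants, adjust) it. Varying more than two offsets
independently is out of scope by design.

Surfaces over the explored `(π_C^NR, π_E^NR)` scatter use
Delaunay-triangulation linear interpolation with no extrapolation beyond
the convex hull — values outside the explored region would fabricate
sensitivity claims. The significance boundary is the `p = α` level set of
the interpolated p-surface (empty when p never crosses α on the hull).
The overlay report renders, per follow-up time, odds-ratio contours, the
significance boundary, credible-region outlines and the two reference
points (missing=smoking at the origin; observed quit rates for MAR), and
emits a JSON verdict per region: the odds-ratio range over the region and
whether any of it crosses the significance boundary ("sensitive") or none
does ("insensitive").

## Numerical and testing choices

Problem sizes in the test suite are chosen to make Monte-Carlo noise
small relative to the asserted tolerances while keeping the default run
fast: 10⁵ samples for HDR coverage (±1 point), 10⁵ participants for
generator calibration (±0.5 point), trial-sized data (n ≈ 600) with
`m = 5` and 9×9 or 5×5 grids for the end-to-end recovery checks. The
parameter-recovery tolerance (0.3 on the log-odds scale) reflects the
sampling noise of imputing ~50 outcomes per arm at `m = 5`, not a claim
about asymptotic accuracy. All stochastic tests are seeded; hypothesis
property tests run derandomized.

## Known limitations

- Only two arms, two follow-up times, binary outcomes; no baseline or
  auxiliary covariates, no passive imputation, no predictive mean
  matching. The engine generalizes to more times via the linkage
  constants, but the implementation does not expose more than two.
- The KDE ignores boundary truncation; HDR coverage is validated
  empirically rather than corrected analytically.
- Automatic calibration of linkage constants to a target between-time
  correlation is not implemented (the diagnostic is).
- The questionnaire itself (UI, storage) is out of scope; this package is
  its computational backend.
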
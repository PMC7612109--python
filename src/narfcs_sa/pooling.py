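"""Analysis-model fits and Rubin's-rules pooling.

The substantive analysis per follow-up time is the unadjusted logistic
regression logit Pr(Y_t = 1 | Z) = alpha_t + beta_t Z, whose arm effect
beta_t on a completed dataset is exactly the log cross-product (odds)
ratio of the 2x2 arm-by-outcome table. Estimates across the m completed
copies are combined by Rubin's rules with the Barnard-Rubin small-sample
degrees of freedom, and the quit rate among nonresponders (pi^NR) is
estimated as the average across copies of the imputed quit proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .impute import MultipleImputations
from .synthetic import TrialDataset

__all__ = [
    "EffectEstimate",
    "PooledResult",
    "PiEstimate",
    "fit_effect_model",
    "rubin_pool",
    "pool_effects",
    "estimate_pi_nr",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Intercept and arm effect (log-odds scale) with the Wald SE of the
    arm effect. Non-finite fields flag an empty cell in the 2x2 table."""

    alpha: float
    beta: float
    se_beta: float
    n: int

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.beta) and np.isfinite(self.se_beta))


@dataclass(frozen=True)
class PooledResult:
    estimate: float          # pooled log-odds ratio
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


@dataclass(frozen=True)
class PiEstimate:
    """Nonresponder quit-rate estimate (percent) for one arm/time: the
    average over imputations of the imputed quit proportion among
    originally-missing participants."""

    arm: int
    time: int
    value: float
    per_imputation: tuple


def fit_effect_model(completed: TrialDataset, time: int) -> EffectEstimate:
    """Logistic regression of the outcome at ``time`` on the arm indicator.

    On completed data this is a saturated model for the 2x2 table, so the
    MLE is available in closed form: beta is the log cross-product ratio
    and its SE is sqrt of the summed reciprocal cell counts. An empty cell
    yields flagged non-finite estimates rather than an exception.
    """
    y = completed.y(time)
    if np.isnan(y).any():
        raise ValueError(f"outcome y{time} still has missing values")
    z = completed.arm
    a = float(np.sum((z == 1) & (y == 1)))  # experimental quit
    b = float(np.sum((z == 1) & (y == 0)))
    c = float(np.sum((z == 0) & (y == 1)))  # control quit
    d = float(np.sum((z == 0) & (y == 0)))
    if min(a, b, c, d) == 0:
        return EffectEstimate(alpha=np.nan, beta=np.nan, se_beta=np.nan, n=completed.n)
    alpha = np.log(c / d)
    beta = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(alpha=float(alpha), beta=float(beta), se_beta=float(se), n=completed.n)


def rubin_pool(estimates: list[EffectEstimate], conf_level: float = 0.95) -> PooledResult:
    """Pool m arm-effect estimates by Rubin's rules.

    qbar = mean estimate; W = mean squared SE; B = sample variance of the
    estimates; T = W + (1 + 1/m) B. Degrees of freedom follow Barnard and
    Rubin's small-sample formula with complete-data df = n - 2. CI and
    two-sided p-value use the t reference distribution.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    bad = [i for i, e in enumerate(estimates) if not e.finite]
    if bad:
        raise ValueError(f"non-finite estimates from imputations {bad}")
    m = len(estimates)
    q = np.array([e.beta for e in estimates])
    u = np.array([e.se_beta**2 for e in estimates])
    qbar = float(q.mean())
    w = float(u.mean())
    if m == 1:
        import warnings

        warnings.warn("pooling a single imputation: no between-imputation variance")
        b = 0.0
    else:
        b = float(q.var(ddof=1))
    t_var = w + (1.0 + 1.0 / m) * b

    dfcom = max(estimates[0].n - 2, 1)
    if b > 0 and m > 1:
        lam = (1.0 + 1.0 / m) * b / t_var
        df_old = (m - 1) / lam**2
        df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = float(dfcom)

    se = np.sqrt(t_var)
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df)
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(qbar) / se, df))
    else:
        p = 0.0 if qbar != 0 else 1.0
    return PooledResult(
        estimate=qbar, within_var=w, between_var=b, total_var=float(t_var),
        df=float(df), m=m, odds_ratio=float(np.exp(qbar)),
        ci_low=float(np.exp(qbar - tcrit * se)), ci_high=float(np.exp(qbar + tcrit * se)),
        p_value=p,
    )


def pool_effects(imps: MultipleImputations, time: int) -> PooledResult:
    """Fit the analysis model on every completed copy and pool."""
    return rubin_pool([fit_effect_model(d, time) for d in imps.datasets])


def estimate_pi_nr(imps: MultipleImputations, arm: int, time: int) -> PiEstimate:
    """Average imputed quit proportion among originally-missing participants.

    Returns a flagged-undefined (NaN) estimate when that arm/time had no
    missing participants to impute.
    """
    original = imps.original
    sel = (original.arm == arm) & (original.m(time) == 1)
    if not sel.any():
        return PiEstimate(arm=arm, time=time, value=float("nan"), per_imputation=())
    props = tuple(float(d.y(time)[sel].mean()) for d in imps.datasets)
    return PiEstimate(arm=arm, time=time, value=100.0 * float(np.mean(props)),
                      per_imputation=props)
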
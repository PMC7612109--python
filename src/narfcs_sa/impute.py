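"""Multiple imputation of two binary outcomes per arm.

Three routines share one chained-equations engine:

* ``missing_equals_smoking`` — the Russell-Standard single imputation that
  sets every missing outcome to smoking (0).
* ``fcs_impute`` — MAR fully conditional specification: each outcome is
  imputed from a logistic regression on the other outcome, separately per
  arm.
* ``narfcs_impute`` — not-at-random FCS: the univariate models additionally
  include the other outcome's missingness indicator (coefficient gamma,
  estimable), and the imputation linear predictor is shifted by a fixed,
  user-chosen log-odds offset delta for the imputed rows themselves. The
  delta offsets are the sensitivity parameters: they encode how the odds of
  quitting among nonresponders differ from responders, conditional on the
  model's covariates, and can never be estimated from the observed data.

Coefficient uncertainty is propagated the way chained-equations software
does: each fit draws one coefficient vector from the asymptotic normal
approximation to the posterior (mean = MLE, covariance = inverse observed
information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .synthetic import ARMS, TrialDataset

logger = logging.getLogger("narfcs_sa")

__all__ = [
    "SPSet",
    "ImputationConfig",
    "MultipleImputations",
    "missing_equals_smoking",
    "fit_logistic",
    "draw_coefficients",
    "narfcs_impute",
    "fcs_impute",
    "build_design",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPSet:
    """The four delta sensitivity parameters (log-odds offsets).

    delta_{time}{arm}: offset added to the imputation linear predictor for
    missing outcomes at that follow-up time in that arm. 0 everywhere
    recovers MAR; large negative values push imputations toward smoking.
    """

    delta_1C: float = 0.0
    delta_1E: float = 0.0
    delta_2C: float = 0.0
    delta_2E: float = 0.0

    def __post_init__(self):
        for name in ("delta_1C", "delta_1E", "delta_2C", "delta_2E"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be a finite real")

    def delta(self, arm: int, time: int) -> float:
        return getattr(self, f"delta_{time}{'C' if arm == 0 else 'E'}")


@dataclass(frozen=True)
class ImputationConfig:
    """m = number of completed copies; n_cycles = sweeps through the variables
    per copy. ``ridge`` stabilizes fits under separation; ``posterior_draws``
    False (a test hook) uses the MLE itself instead of a posterior draw."""

    m: int = 20
    n_cycles: int = 10
    seed: int = 0
    ridge: float = 1e-4
    posterior_draws: bool = True

    def __post_init__(self):
        if self.m < 1 or self.n_cycles < 1:
            raise ValueError("m and n_cycles must be >= 1")


@dataclass
class MultipleImputations:
    """m completed copies of a trial dataset plus the settings that made them."""

    datasets: list  # of TrialDataset, all complete
    original: TrialDataset
    sp: SPSet | None
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.datasets)


# ---------------------------------------------------------------------------
# Missing = smoking
# ---------------------------------------------------------------------------

def missing_equals_smoking(data: TrialDataset) -> TrialDataset:
    """Set every missing outcome to smoking (0); observed cells untouched."""
    frame = data.frame.copy()
    for c in ("y1", "y2"):
        frame[c] = frame[c].fillna(0.0)
    return TrialDataset(frame)


# ---------------------------------------------------------------------------
# Logistic fitting and posterior coefficient draws
# ---------------------------------------------------------------------------

def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                 max_iter: int = 50, tol: float = 1e-8):
    """Newton-Raphson logistic fit returning (beta, covariance).

    With ridge > 0 the log-likelihood is penalized by -ridge/2 * ||beta||^2
    (intercept included), which keeps estimates finite under separation.
    Raises on non-convergence so callers can fall back to a ridge refit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    penalty = ridge * np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        info = (X.T * w) @ X + penalty
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular information matrix") from err
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            if np.max(np.abs(beta)) > 35.0 and ridge == 0.0:
                raise RuntimeError("divergent coefficients (separation)")
            eta = X @ beta
            w = expit(eta) * (1.0 - expit(eta))
            info = (X.T * w) @ X + penalty
            cov = np.linalg.inv(info)
            return beta, cov
    raise RuntimeError("logistic fit did not converge")


def draw_coefficients(response: np.ndarray, design: np.ndarray,
                      rng: np.random.Generator, ridge: float = 1e-4,
                      posterior_draw: bool = True) -> np.ndarray:
    """MLE logistic fit, then one draw from N(MLE, inverse information).

    Perfect separation or non-convergence triggers a refit with a small
    ridge penalty (logged as a warning). With ``posterior_draw`` False the
    MLE itself is returned — used by tests to pin the fit deterministically.
    """
    try:
        beta, cov = fit_logistic(design, response, ridge=0.0)
    except RuntimeError as err:
        logger.warning("logistic fit unstable (%s); refitting with ridge %.1e", err, ridge)
        beta, cov = fit_logistic(design, response, ridge=ridge)
    if not posterior_draw:
        return beta
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    return beta + chol @ rng.standard_normal(len(beta))


# ---------------------------------------------------------------------------
# Chained-equations engine
# ---------------------------------------------------------------------------

def build_design(y_other: np.ndarray, m_other: np.ndarray, mnar: bool) -> np.ndarray:
    """Model matrix for one univariate imputation model.

    MAR (``mnar`` False): intercept + other outcome. MNAR: additionally the
    other outcome's missingness indicator (its gamma coefficient is
    estimable because the data are nonmonotone)."""
    cols = [np.ones_like(y_other), y_other]
    if mnar:
        cols.append(m_other.astype(float))
    return np.column_stack(cols)


def _substream(seed: int, imp: int, cycle: int, var: int) -> np.random.Generator:
    # independent substream per (imputation, cycle, variable): results do not
    # depend on evaluation order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(imp, cycle, var)))


def _impute_arm(frame, arm_mask, sp: SPSet | None, cfg: ImputationConfig,
                imp_index: int, arm: int, mnar: bool,
                coef_log: list | None = None) -> np.ndarray:
    """Run the chained sweeps for one arm of one imputation; returns the
    completed (n_arm, 2) outcome matrix."""
    y = frame.loc[arm_mask, ["y1", "y2"]].to_numpy(dtype=float)
    miss = np.isnan(y)
    for j in range(2):
        if miss[:, j].any() and not (~miss[:, j]).any():
            raise ValueError(f"arm {arm}, outcome y{j + 1}: no observed values to fit on")

    # initialize missing cells from the within-arm observed marginal
    current = y.copy()
    for j in range(2):
        if miss[:, j].any():
            rng = _substream(cfg.seed, imp_index, 0, 2 * arm + j)
            observed = y[~miss[:, j], j]
            current[miss[:, j], j] = rng.choice(observed, size=int(miss[:, j].sum()))

    for cycle in range(1, cfg.n_cycles + 1):
        for j in range(2):
            if not miss[:, j].any():
                continue
            k = 1 - j
            fit_rows = ~miss[:, j]
            X = build_design(current[:, k], miss[:, k], mnar)
            rng = _substream(cfg.seed, imp_index, cycle, 2 * arm + j)
            beta = draw_coefficients(y[fit_rows, j], X[fit_rows], rng,
                                     ridge=cfg.ridge, posterior_draw=cfg.posterior_draws)
            if coef_log is not None:
                coef_log.append((imp_index, cycle, arm, j + 1, beta.copy()))
            eta = X[miss[:, j]] @ beta
            if mnar:
                eta = eta + sp.delta(arm, j + 1)  # M_j = 1 on every imputed row
            current[miss[:, j], j] = (rng.random(int(miss[:, j].sum())) < expit(eta)).astype(float)
    return current


def _chained_impute(data: TrialDataset, sp: SPSet | None, cfg: ImputationConfig,
                    mnar: bool, coef_log: list | None = None) -> MultipleImputations:
    frame = data.frame
    datasets = []
    for i in range(cfg.m):
        completed = frame.copy()
        for z in ARMS:
            arm_mask = frame["arm"].to_numpy() == z
            if not arm_mask.any():
                continue
            completed.loc[arm_mask, ["y1", "y2"]] = _impute_arm(
                frame, arm_mask, sp, cfg, i, z, mnar, coef_log)
        datasets.append(TrialDataset(completed))
    return MultipleImputations(datasets=datasets, original=data.copy(), sp=sp, config=cfg)


def narfcs_impute(data: TrialDataset, sp: SPSet, cfg: ImputationConfig,
                  coef_log: list | None = None) -> MultipleImputations:
    """NARFCS multiple imputation with fixed delta offsets, arms separate.

    Per copy: missing cells start from within-arm observed-marginal draws;
    each sweep refits each outcome's logistic model on its observed rows
    (regressors: the other outcome's current values and missingness
    indicator), draws coefficients, and imputes missing values as Bernoulli
    with logit = linear predictor + delta for that arm/time. The delta
    regressor M_j is 0 on every fitted row, so the offsets never touch the
    estimable coefficients.
    """
    return _chained_impute(data, sp, cfg, mnar=True, coef_log=coef_log)


def fcs_impute(data: TrialDataset, cfg: ImputationConfig,
               coef_log: list | None = None) -> MultipleImputations:
    """MAR fully-conditional-specification imputation: same engine as
    ``narfcs_impute`` but the univariate models drop both missingness
    indicators and all delta offsets."""
    return _chained_impute(data, None, cfg, mnar=False, coef_log=coef_log)
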
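"""Expert elicitation: questionnaire responses to bivariate truncated-normal priors.

Each expert answers, per follow-up time and per arm, with the most likely
nonresponder quit rate (the mode of a truncated normal curve over 0-100%)
and a certainty score that maps linearly to the curve's standard deviation.
One further answer — the expert's updated most likely control-arm value
after being told the experimental-arm rate sits at its upper quartile —
pins the between-arm correlation: marking the displayed control upper
quartile corresponds to correlation 1, staying put to correlation 0. The
correlation is elicited once (first follow-up) and reused at the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal, norm

__all__ = [
    "MarginalPrior",
    "ExpertResponse",
    "BivariatePrior",
    "CertaintyMap",
    "certainty_to_sd",
    "derive_correlation",
    "build_bivariate_prior",
    "sample_prior",
    "expert_priors",
    "RHO_CLIP",
    "Z_UPPER_QUARTILE",
]

RHO_CLIP = 0.99  # stability clip applied before HDR construction
Z_UPPER_QUARTILE = float(norm.ppf(0.75))  # ~0.6745


@dataclass(frozen=True)
class CertaintyMap:
    """Linear certainty-score -> standard-deviation mapping (percent points).

    Full certainty (score 100) gives sd_min; no certainty gives sd_max.
    The questionnaire app's exact mapping is a front-end choice, so the
    endpoints are configuration with these defaults.
    """

    sd_min: float = 1.0
    sd_max: float = 30.0


@dataclass(frozen=True)
class MarginalPrior:
    """Truncated-normal marginal on a nonresponder quit rate (percent)."""

    mode: float
    sd: float
    bounds: tuple = (0.0, 100.0)

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo <= self.mode <= hi:
            raise ValueError("mode must lie within the truncation bounds")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class ExpertResponse:
    """One expert's questionnaire answers.

    modes/certainties are keyed "1C", "1E", "2C", "2E" (time then arm);
    updated_mode_1C is the Question-3 answer; rationale is carried verbatim.
    """

    expert_id: str
    modes: dict
    certainties: dict
    updated_mode_1C: float
    rationale: str = ""

    KEYS = ("1C", "1E", "2C", "2E")

    def __post_init__(self):
        for k in self.KEYS:
            if k not in self.modes or k not in self.certainties:
                raise ValueError(f"response {self.expert_id} lacks answers for {k}")
            if not 0 <= self.modes[k] <= 100:
                raise ValueError(f"mode {k} outside [0, 100]")
            if not 0 <= self.certainties[k] <= 100:
                raise ValueError(f"certainty {k} outside the slider range [0, 100]")
        if not 0 <= self.updated_mode_1C <= 100:
            raise ValueError("updated_mode_1C outside [0, 100]")


@dataclass(frozen=True)
class BivariatePrior:
    """Truncated bivariate normal over (pi_C, pi_E) in percent.

    The underlying (pre-truncation) normal takes the elicited modes as
    means and elicited sds as standard deviations; truncation to the
    region then renormalizes the density.
    """

    control: MarginalPrior
    experimental: MarginalPrior
    rho: float

    def __post_init__(self):
        if abs(self.rho) > RHO_CLIP + 1e-12:
            raise ValueError(f"|rho| must be <= {RHO_CLIP} (clip first)")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.control.mode, self.experimental.mode])

    @property
    def cov(self) -> np.ndarray:
        s1, s2 = self.control.sd, self.experimental.sd
        return np.array([[s1 * s1, self.rho * s1 * s2],
                         [self.rho * s1 * s2, s2 * s2]])

    @property
    def bounds(self) -> tuple:
        return (self.control.bounds, self.experimental.bounds)

    def _mvn(self):
        return multivariate_normal(self.mean, self.cov)

    def normalizing_mass(self) -> float:
        (l1, u1), (l2, u2) = self.bounds
        return float(self._mvn().cdf([u1, u2], lower_limit=[l1, l2]))

    def pdf(self, points: np.ndarray) -> np.ndarray:
        """Density of the truncated distribution; zero outside the region."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dens = self._mvn().pdf(pts) / self.normalizing_mass()
        (l1, u1), (l2, u2) = self.bounds
        inside = ((pts[:, 0] >= l1) & (pts[:, 0] <= u1)
                  & (pts[:, 1] >= l2) & (pts[:, 1] <= u2))
        return np.where(inside, dens, 0.0)

    def swap(self) -> "BivariatePrior":
        return BivariatePrior(self.experimental, self.control, self.rho)


# ---------------------------------------------------------------------------
# Elicitation operations
# ---------------------------------------------------------------------------

def certainty_to_sd(score: float, cfg: CertaintyMap = CertaintyMap()) -> float:
    """Map a certainty slider score in [0, 100] to an sd in percent points,
    strictly decreasing: sd = sd_max - (score/100)(sd_max - sd_min)."""
    if not 0 <= score <= 100:
        raise ValueError("certainty score must lie in [0, 100]")
    return cfg.sd_max - (score / 100.0) * (cfg.sd_max - cfg.sd_min)


def derive_correlation(marginal_C: MarginalPrior, updated_mode: float,
                       clip: float = RHO_CLIP) -> float:
    """Between-arm correlation from the Question-3 updated control mode.

    For a bivariate normal, learning that pi_E sits at its upper quartile
    shifts the conditional mean of pi_C by rho * z_0.75 * sd_C. Inverting:
    rho = (updated_mode - mode_C) / (z_0.75 * sd_C), so no shift gives 0 and
    marking the displayed upper quartile gives exactly 1, which is then
    clipped to +/-0.99 so the HDR can be constructed.
    """
    raw = (updated_mode - marginal_C.mode) / (Z_UPPER_QUARTILE * marginal_C.sd)
    return float(np.clip(raw, -clip, clip))


def build_bivariate_prior(marg_C: MarginalPrior, marg_E: MarginalPrior,
                          rho: float) -> BivariatePrior:
    """Assemble the truncated bivariate normal prior from two marginals and
    the derived correlation."""
    return BivariatePrior(marg_C, marg_E, rho)


def sample_prior(prior: BivariatePrior, n: int, seed=None,
                 min_acceptance: float = 1e-3) -> np.ndarray:
    """Draw exactly n points from the truncated prior by rejection sampling.

    Raises with diagnostics when the acceptance rate of the underlying
    normal falls below ``min_acceptance`` (pathological parameters).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    (l1, u1), (l2, u2) = prior.bounds
    mean, cov = prior.mean, prior.cov
    chol = np.linalg.cholesky(cov)
    out = np.empty((n, 2))
    got, proposed = 0, 0
    while got < n:
        batch = max(2 * (n - got), 1000)
        z = rng.standard_normal((batch, 2))
        pts = mean + z @ chol.T
        keep = ((pts[:, 0] >= l1) & (pts[:, 0] <= u1)
                & (pts[:, 1] >= l2) & (pts[:, 1] <= u2))
        proposed += batch
        take = min(int(keep.sum()), n - got)
        out[got:got + take] = pts[keep][:take]
        got += take
        if proposed >= 10000 and (got / proposed) < min_acceptance:
            raise RuntimeError(
                f"rejection acceptance rate {got / proposed:.2e} below floor "
                f"{min_acceptance}; prior mass barely intersects {prior.bounds}")
    return out


def expert_priors(resp: ExpertResponse, cfg: CertaintyMap = CertaintyMap(),
                  rho_override: float | None = None) -> dict:
    """Build one expert's bivariate priors for both follow-up times.

    The correlation is derived once from the first-follow-up Question-3
    answer and reused at the second follow-up time (overridable).
    """
    margs = {k: MarginalPrior(resp.modes[k], certainty_to_sd(resp.certainties[k], cfg))
             for k in ExpertResponse.KEYS}
    rho = (derive_correlation(margs["1C"], resp.updated_mode_1C)
           if rho_override is None else float(np.clip(rho_override, -RHO_CLIP, RHO_CLIP)))
    return {
        1: build_bivariate_prior(margs["1C"], margs["1E"], rho),
        2: build_bivariate_prior(margs["2C"], margs["2E"], rho),
    }
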
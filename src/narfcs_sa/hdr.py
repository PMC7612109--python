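"""Highest density regions and linear opinion pooling.

A (1-alpha) HDR is the smallest region containing 1-alpha of the
probability mass — the superlevel set of the density at the threshold
equal to the alpha-quantile of density values at sample points (the
density-quantile construction). Densities come from a fast binned kernel
density estimate with normal-reference (per-axis Silverman) bandwidths, so
regions can be built from the millions of samples a smooth pooled contour
needs. The pooled (consensus) prior is the equal-weight mixture of the
experts' priors, emulated by concatenating per-expert samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from skimage.measure import find_contours

from .elicitation import BivariatePrior, sample_prior

__all__ = [
    "KDEConfig",
    "KDE2D",
    "HDRRegion",
    "PooledPrior",
    "kde2d",
    "hdr_contours",
    "pool_experts",
    "region_contains",
]

MIN_SAMPLES = 100


@dataclass(frozen=True)
class KDEConfig:
    """Grid resolution and bandwidth multiplier for the binned KDE.

    Bandwidth per axis is ``bw_mult * sigma_j * n^(-1/6)`` (normal reference
    in two dimensions); the evaluation grid pads the sample range by
    ``pad_bandwidths`` bandwidths so mass near the edge is not clipped.
    """

    grid_size: int = 256
    bw_mult: float = 1.0
    pad_bandwidths: float = 4.0


class KDE2D:
    """Binned 2-D Gaussian KDE evaluated on a regular grid."""

    def __init__(self, samples: np.ndarray, cfg: KDEConfig = KDEConfig()):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array")
        n = len(samples)
        sd = samples.std(axis=0, ddof=1)
        if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
            raise ValueError("degenerate samples: zero variance in a coordinate")
        self.bandwidth = cfg.bw_mult * sd * n ** (-1.0 / 6.0)
        lo = samples.min(axis=0) - cfg.pad_bandwidths * self.bandwidth
        hi = samples.max(axis=0) + cfg.pad_bandwidths * self.bandwidth
        self.x = np.linspace(lo[0], hi[0], cfg.grid_size)
        self.y = np.linspace(lo[1], hi[1], cfg.grid_size)
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        counts, _, _ = np.histogram2d(samples[:, 0], samples[:, 1],
                                      bins=[cfg.grid_size, cfg.grid_size],
                                      range=[[lo[0] - dx / 2, hi[0] + dx / 2],
                                             [lo[1] - dy / 2, hi[1] + dy / 2]])
        sigma_bins = self.bandwidth / np.array([dx, dy])
        self.density = gaussian_filter(counts / (n * dx * dy), sigma=sigma_bins,
                                       mode="constant")
        self._interp = RegularGridInterpolator(
            (self.x, self.y), self.density, bounds_error=False, fill_value=0.0)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self._interp(np.atleast_2d(np.asarray(points, dtype=float)))


@dataclass
class HDRRegion:
    """One highest-density credible region.

    The region is the superlevel set {density >= density_threshold};
    ``contours`` holds its boundary polylines in percent coordinates,
    clipped to the unit square of quit rates [0, 100]^2.
    """

    coverage: float
    density_threshold: float
    contours: list
    kde: KDE2D
    n_samples: int

    def area(self) -> float:
        """Area of the superlevel set, by grid quadrature."""
        dx = self.kde.x[1] - self.kde.x[0]
        dy = self.kde.y[1] - self.kde.y[0]
        return float((self.kde.density >= self.density_threshold).sum() * dx * dy)


@dataclass
class PooledPrior:
    """Linear opinion pool: mixture of the experts' priors, carried as the
    concatenated per-expert samples in weight proportion."""

    priors: list
    weights: np.ndarray
    samples: np.ndarray


def kde2d(samples: np.ndarray, cfg: KDEConfig = KDEConfig()) -> KDE2D:
    return KDE2D(samples, cfg)


def hdr_contours(samples: np.ndarray, coverages=(0.5, 0.9),
                 cfg: KDEConfig = KDEConfig(),
                 clip_bounds=((0.0, 100.0), (0.0, 100.0))) -> list[HDRRegion]:
    """Construct HDRs at the requested coverage levels from samples.

    Threshold for coverage 1-alpha is the alpha-quantile of KDE density
    values at the sample points; contour polylines are extracted from the
    density grid and clipped to ``clip_bounds``. Regions at higher coverage
    have lower thresholds, so they nest geometrically.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {len(samples)}")
    kde = KDE2D(samples, cfg)
    dens_at = kde(samples)
    regions = []
    for cov in coverages:
        if not 0 < cov < 1:
            raise ValueError("coverage must lie in (0, 1)")
        threshold = float(np.quantile(dens_at, 1.0 - cov))
        contours = _extract_contours(kde, threshold, clip_bounds)
        regions.append(HDRRegion(coverage=cov, density_threshold=threshold,
                                 contours=contours, kde=kde, n_samples=len(samples)))
    return regions


def _extract_contours(kde: KDE2D, threshold: float, clip_bounds) -> list:
    lines = find_contours(kde.density, threshold)
    out = []
    (xl, xu), (yl, yu) = clip_bounds
    for line in lines:
        # grid indices -> data coordinates
        xs = np.interp(line[:, 0], np.arange(len(kde.x)), kde.x)
        ys = np.interp(line[:, 1], np.arange(len(kde.y)), kde.y)
        pts = np.column_stack([np.clip(xs, xl, xu), np.clip(ys, yl, yu)])
        out.append(pts)
    return out


def pool_experts(priors: list[BivariatePrior], n_per_expert: int = 100_000,
                 weights=None, seed=None) -> PooledPrior:
    """Sample each expert's prior and concatenate in weight proportion.

    Equal weights give every expert the same sample count (equal
    contribution to the consensus); unequal weights change the proportion
    of samples per expert. Sample counts are rounded by largest remainder
    so they sum to len(priors) * n_per_expert exactly.
    """
    if len(priors) == 0:
        raise ValueError("need at least one expert prior")
    k = len(priors)
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    total = k * n_per_expert
    raw = weights * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1

    seeds = np.random.SeedSequence(seed).spawn(k)
    parts = [sample_prior(p, int(c), seed=s)
             for p, c, s in zip(priors, counts, seeds) if c > 0]
    return PooledPrior(priors=list(priors), weights=weights,
                       samples=np.concatenate(parts, axis=0))


def region_contains(region: HDRRegion, point) -> bool:
    """True iff the KDE density at ``point`` reaches the region threshold."""
    return bool(region.kde(point)[0] >= region.density_threshold)
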
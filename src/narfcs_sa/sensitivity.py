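"""The two-dimensional delta-grid sensitivity analysis.

The four sensitivity parameters cannot all vary freely (the grid would be
unmanageable), so the analysis varies the two first-follow-up offsets
(delta_1C, delta_1E) over a grid and links the second-follow-up offsets to
them (delta_2z = delta_1z at the default linkage constant 1). For every
grid point the missing outcomes are multiply imputed under NARFCS, the
arm effect at each follow-up time is pooled by Rubin's rules, and the
unidentifiable offsets are mapped to the interpretable nonresponder quit
rates pi^NR estimated from the imputed data. Effect-size and p-value
surfaces over the (pi_C, pi_E) plane, the p = alpha significance boundary,
and overlays against elicited credible regions then show whether the
trial's conclusion survives plausible departures from MAR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError
from skimage.measure import find_contours

from .impute import ImputationConfig, SPSet, narfcs_impute
from .pooling import estimate_pi_nr, pool_effects
from .synthetic import ARMS, TIMES, TrialDataset

logger = logging.getLogger("narfcs_sa")

__all__ = [
    "SPGridConfig",
    "SAResult",
    "build_sp_grid",
    "run_sensitivity",
    "between_time_correlation",
    "contour_surface",
    "significance_boundary",
    "overlay_report",
]


@dataclass(frozen=True)
class SPGridConfig:
    """Grid of sensitivity-parameter sets.

    delta_range/step define the marginal values for delta_1C and delta_1E;
    the grid is their Cartesian product. ``linkage_constants`` (one per
    later follow-up time) tie later offsets to the first time via
    delta_1z = c * delta_tz, i.e. delta_tz = delta_1z / c; the default
    c = 1 sets them equal.
    """

    delta_range: tuple = (-4.0, 4.0)
    step: float = 0.5
    linkage_constants: tuple = (1.0,)

    def __post_init__(self):
        lo, hi = self.delta_range
        if not (np.isfinite(lo) and np.isfinite(hi) and hi >= lo):
            raise ValueError("delta_range endpoints must be finite with high >= low")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if any(c == 0 for c in self.linkage_constants):
            raise ValueError("linkage constants must be nonzero")

    @property
    def values(self) -> np.ndarray:
        lo, hi = self.delta_range
        count = int(np.floor((hi - lo) / self.step + 1e-9)) + 1
        return lo + self.step * np.arange(count)


@dataclass
class SAResult:
    """One row per sensitivity-parameter set: the four deltas, pooled
    effect/OR/CI/p per follow-up time, and the four pi^NR estimates."""

    table: pd.DataFrame
    grid_config: SPGridConfig | None = None
    imp_config: ImputationConfig | None = None

    COLUMNS = (
        ["delta_1C", "delta_1E", "delta_2C", "delta_2E"]
        + [f"{q}_{t}" for t in TIMES for q in ("beta", "or", "ci_low", "ci_high", "p")]
        + [f"pi_{t}{a}" for t in TIMES for a in ("C", "E")]
        + ["error"]
    )


def build_sp_grid(cfg: SPGridConfig = SPGridConfig()) -> list[SPSet]:
    """Cartesian product of delta_1C x delta_1E, delta_1C-major, with the
    second-time offsets derived through the linkage constant."""
    c1 = cfg.linkage_constants[0]
    grid = []
    for d1c in cfg.values:
        for d1e in cfg.values:
            grid.append(SPSet(delta_1C=d1c, delta_1E=d1e,
                              delta_2C=d1c / c1, delta_2E=d1e / c1))
    return grid


def _row_seed(master: int, sp: SPSet) -> int:
    """Seed for one grid row, a pure function of (master seed, deltas)."""
    key = []
    for d in (sp.delta_1C, sp.delta_1E, sp.delta_2C, sp.delta_2E):
        bits = int(np.float64(d).view(np.uint64))
        key.extend([bits & 0xFFFFFFFF, bits >> 32])
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_sensitivity(data: TrialDataset, grid: list[SPSet],
                    imp_cfg: ImputationConfig) -> SAResult:
    """NARFCS-impute, pool, and estimate pi^NR for every grid point.

    Each row runs on its own seed substream derived from the master seed
    and the row's delta values (not its grid position), so any subset of
    rows recomputed in isolation matches the full run. Per-row failures
    are recorded in the row's ``error`` column and the run continues.
    """
    rows = []
    for idx, sp in enumerate(grid):
        row = {"delta_1C": sp.delta_1C, "delta_1E": sp.delta_1E,
               "delta_2C": sp.delta_2C, "delta_2E": sp.delta_2E, "error": ""}
        row_seed = _row_seed(imp_cfg.seed, sp)
        cfg = ImputationConfig(m=imp_cfg.m, n_cycles=imp_cfg.n_cycles, seed=row_seed,
                               ridge=imp_cfg.ridge, posterior_draws=imp_cfg.posterior_draws)
        try:
            imps = narfcs_impute(data, sp, cfg)
            for t in TIMES:
                pooled = pool_effects(imps, t)
                row[f"beta_{t}"] = pooled.estimate
                row[f"or_{t}"] = pooled.odds_ratio
                row[f"ci_low_{t}"] = pooled.ci_low
                row[f"ci_high_{t}"] = pooled.ci_high
                row[f"p_{t}"] = pooled.p_value
                for z, a in zip(ARMS, ("C", "E")):
                    row[f"pi_{t}{a}"] = estimate_pi_nr(imps, z, t).value
        except Exception as err:  # row-level containment
            logger.warning("grid row %d (%s) failed: %s", idx, sp, err)
            row["error"] = str(err)
        rows.append(row)
    table = pd.DataFrame(rows).reindex(columns=list(SAResult.COLUMNS))
    return SAResult(table=table, grid_config=None, imp_config=imp_cfg)


def between_time_correlation(res: SAResult, arm: str) -> tuple[float, int]:
    """Sample correlation across grid rows between the first- and
    second-follow-up pi^NR estimates for one arm ("C" or "E").

    Diagnoses the delta_2z = delta_1z linkage: it should normally yield a
    strongly positive between-time correlation. Rows with undefined pi are
    excluded; the count excluded is returned alongside the correlation.
    """
    if arm not in ("C", "E"):
        raise ValueError("arm must be 'C' or 'E'")
    x = res.table[f"pi_1{arm}"].to_numpy(dtype=float)
    y = res.table[f"pi_2{arm}"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("need at least 3 rows with defined pi estimates")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return r, excluded


# ---------------------------------------------------------------------------
# Surfaces and boundaries over the (pi_C, pi_E) plane
# ---------------------------------------------------------------------------

@dataclass
class Surface:
    """A quantity interpolated over the explored (pi_C, pi_E) scatter.

    Linear barycentric interpolation on the Delaunay triangulation; NaN
    outside the convex hull (no extrapolation: sensitivity claims are never
    fabricated beyond the explored region).
    """

    interpolator: LinearNDInterpolator
    points: np.ndarray
    values: np.ndarray

    def __call__(self, pts) -> np.ndarray:
        return self.interpolator(np.atleast_2d(np.asarray(pts, dtype=float)))

    def grid(self, resolution: int = 201):
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        xs = np.linspace(lo[0], hi[0], resolution)
        ys = np.linspace(lo[1], hi[1], resolution)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        zz = self.interpolator(np.column_stack([xx.ravel(), yy.ravel()]))
        return xs, ys, zz.reshape(xx.shape)


def contour_surface(res: SAResult, time: int, quantity: str = "odds_ratio") -> Surface:
    """Interpolate a pooled quantity over the (pi_C, pi_E) scatter."""
    col = {"odds_ratio": f"or_{time}", "p_value": f"p_{time}", "beta": f"beta_{time}"}
    if quantity not in col:
        raise ValueError(f"quantity must be one of {sorted(col)}")
    t = res.table
    pts = t[[f"pi_{time}C", f"pi_{time}E"]].to_numpy(dtype=float)
    vals = t[col[quantity]].to_numpy(dtype=float)
    ok = np.isfinite(pts).all(axis=1) & np.isfinite(vals)
    pts, vals = pts[ok], vals[ok]
    if len(pts) < 3:
        raise ValueError("need at least 3 valid (pi_C, pi_E) points")
    try:
        interp = LinearNDInterpolator(pts, vals)
    except QhullError as err:
        raise ValueError(f"degenerate (collinear) pi scatter: {err}") from err
    if interp.tri.simplices.size == 0:
        raise ValueError("degenerate (collinear) pi scatter")
    return Surface(interpolator=interp, points=pts, values=vals)


def significance_boundary(res: SAResult, time: int, alpha: float = 0.05,
                          resolution: int = 201) -> list[np.ndarray]:
    """Level set p = alpha of the interpolated p-value surface.

    Returns polylines in (pi_C, pi_E) percent coordinates; an empty list
    means p never crosses alpha anywhere on the explored hull.
    """
    surf = contour_surface(res, time, "p_value")
    xs, ys, zz = surf.grid(resolution)
    filled = np.where(np.isfinite(zz), zz, np.nanmedian(surf.values))
    lines = find_contours(filled, alpha)
    out = []
    for line in lines:
        px = np.interp(line[:, 0], np.arange(len(xs)), xs)
        py = np.interp(line[:, 1], np.arange(len(ys)), ys)
        pts = np.column_stack([px, py])
        inside = np.isfinite(surf(pts)).ravel()
        if inside.any():
            out.append(pts[inside])
    return out


def overlay_report(res: SAResult, regions=None, reference_points=None,
                   alpha: float = 0.05, out_dir=None) -> dict:
    """Figures plus a machine-readable summary per follow-up time.

    Each figure overlays the odds-ratio contours, the p = alpha boundary,
    any credible regions, and the two reference points (missing=smoking at
    the origin, the observed quit rates for MAR). The summary reports, per
    region, the range of the odds ratio over the region and whether any of
    it crosses into p < alpha territory — "sensitive" — or stays entirely
    where p > alpha — "insensitive".
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = regions or []
    reference_points = reference_points or []
    summary = {"alpha": alpha, "times": {}}
    for t in TIMES:
        or_surf = contour_surface(res, t, "odds_ratio")
        p_surf = contour_surface(res, t, "p_value")
        boundary = significance_boundary(res, t, alpha)

        fig, ax = plt.subplots(figsize=(6, 6))
        xs, ys, zz = or_surf.grid()
        cs = ax.contour(xs, ys, zz.T, levels=10, colors="black", linewidths=0.8)
        ax.clabel(cs, fontsize=7, fmt="%.2f")
        for line in boundary:
            ax.plot(line[:, 0], line[:, 1], "r--", lw=1.5)
        for reg in regions:
            for contour in reg.contours:
                ax.plot(contour[:, 0], contour[:, 1], lw=1.2)
        for px, py in reference_points:
            ax.plot(px, py, "ro", ms=6)
        ax.set_xlabel("nonresponder quit rate, control (%)")
        ax.set_ylabel("nonresponder quit rate, experimental (%)")
        ax.set_title(f"sensitivity analysis, follow-up {t}")
        if out_dir is not None:
            fig.savefig(f"{out_dir}/sa_time{t}.png", dpi=150)
        plt.close(fig)

        verdicts = []
        for reg in regions:
            probe = _region_probe_points(reg)
            or_vals = or_surf(probe).ravel()
            p_vals = p_surf(probe).ravel()
            ok = np.isfinite(or_vals) & np.isfinite(p_vals)
            if not ok.any():
                verdicts.append({"coverage": reg.coverage, "verdict": "outside explored surface"})
                continue
            crosses = bool((p_vals[ok] < alpha).any())
            verdicts.append({
                "coverage": reg.coverage,
                "or_range": [float(np.min(or_vals[ok])), float(np.max(or_vals[ok]))],
                "crosses_significance": crosses,
                "verdict": "sensitive" if crosses else "insensitive",
            })
        summary["times"][t] = {
            "boundary_empty": len(boundary) == 0,
            "regions": verdicts,
        }
    if out_dir is not None:
        with open(f"{out_dir}/sa_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary


def _region_probe_points(region, per_axis: int = 40) -> np.ndarray:
    """Grid points inside the HDR superlevel set, for range queries."""
    kde = region.kde
    xs = np.linspace(kde.x[0], kde.x[-1], per_axis)
    ys = np.linspace(kde.y[0], kde.y[-1], per_axis)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    dens = kde(pts)
    inside = dens >= region.density_threshold
    if not inside.any():
        return pts[np.argmax(dens)][None, :]
    return pts[inside]
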
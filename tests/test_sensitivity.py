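import numpy as np
import pandas as pd
import pytest

from narfcs_sa import (
    ImputationConfig,
    SPGridConfig,
    SPSet,
    between_time_correlation,
    build_sp_grid,
    contour_surface,
    fit_effect_model,
    hdr_contours,
    overlay_report,
    run_sensitivity,
    sample_prior,
    significance_boundary,
)
from narfcs_sa.sensitivity import SAResult, _row_seed


def _planar_result(values_fn, n_side=7):
    """SAResult whose pi scatter is a grid and whose surfaces are planes."""
    pis = np.linspace(5, 75, n_side)
    rows = []
    for pc in pis:
        for pe in pis:
            v = values_fn(pc, pe)
            rows.append({
                "delta_1C": 0.0, "delta_1E": 0.0, "delta_2C": 0.0, "delta_2E": 0.0,
                "beta_1": np.log(v["or"]), "or_1": v["or"], "ci_low_1": v["or"] * 0.8,
                "ci_high_1": v["or"] * 1.2, "p_1": v["p"],
                "beta_2": np.log(v["or"]), "or_2": v["or"], "ci_low_2": v["or"] * 0.8,
                "ci_high_2": v["or"] * 1.2, "p_2": v["p"],
                "pi_1C": pc, "pi_1E": pe, "pi_2C": pc * 0.8, "pi_2E": pe * 0.8,
                "error": "",
            })
    return SAResult(table=pd.DataFrame(rows))


class TestGrid:
    def test_default_grid_has_289_sets(self):
        grid = build_sp_grid(SPGridConfig())
        assert len(grid) == 289
        deltas = sorted({sp.delta_1C for sp in grid})
        assert np.allclose(deltas, np.arange(-4, 4.5, 0.5))

    def test_point_grid(self):
        grid = build_sp_grid(SPGridConfig(delta_range=(0.0, 0.0)))
        assert grid == [SPSet(0.0, 0.0, 0.0, 0.0)]

    def test_three_by_three_enumeration(self):
        grid = build_sp_grid(SPGridConfig(delta_range=(-1, 1), step=1.0))
        assert len(grid) == 9
        # delta_1C-major ordering
        assert [sp.delta_1C for sp in grid] == [-1, -1, -1, 0, 0, 0, 1, 1, 1]
        assert [sp.delta_1E for sp in grid] == [-1, 0, 1] * 3

    def test_unit_linkage_ties_times_exactly(self):
        for sp in build_sp_grid(SPGridConfig(delta_range=(-2, 2), step=0.5)):
            assert sp.delta_2C == sp.delta_1C
            assert sp.delta_2E == sp.delta_1E

    def test_linkage_constant_scales_second_time(self):
        grid = build_sp_grid(SPGridConfig(delta_range=(-2, 2), step=1.0,
                                          linkage_constants=(2.0,)))
        for sp in grid:
            assert sp.delta_2C == sp.delta_1C / 2.0
            assert sp.delta_2E == sp.delta_1E / 2.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SPGridConfig(step=0.0)
        with pytest.raises(ValueError):
            SPGridConfig(delta_range=(2.0, -2.0))


@pytest.fixture(scope="module")
def small_run(mnar_trial):
    data, _ = mnar_trial
    grid = build_sp_grid(SPGridConfig(delta_range=(-2, 2), step=1.0))
    cfg = ImputationConfig(m=5, n_cycles=5, seed=42)
    return data, grid, cfg, run_sensitivity(data, grid, cfg)


class TestRunSensitivity:

    def test_row_count_and_no_failures(self, small_run):
        _, grid, _, res = small_run
        assert len(res.table) == len(grid)
        assert (res.table["error"] == "").all()
        pis = res.table[["pi_1C", "pi_1E", "pi_2C", "pi_2E"]].to_numpy()
        assert ((pis >= 0) & (pis <= 100)).all()

    def test_master_seed_reproducibility(self, small_run):
        data, grid, cfg, res = small_run
        again = run_sensitivity(data, grid, cfg)
        pd.testing.assert_frame_equal(res.table, again.table)

    def test_isolated_subset_matches_full_run(self, small_run):
        data, grid, cfg, res = small_run
        sub = run_sensitivity(data, grid[7:8], cfg)
        pd.testing.assert_frame_equal(sub.table,
                                      res.table.iloc[7:8].reset_index(drop=True))

    def test_pi_monotone_in_own_delta(self, small_run):
        _, _, _, res = small_run
        t = res.table
        for d1e in (-2.0, 0.0, 2.0):
            col = t.loc[t["delta_1E"] == d1e].sort_values("delta_1C")["pi_1C"].to_numpy()
            assert np.all(np.diff(col) > -5.0)
            assert col[-1] > col[0]

    def test_mar_point_recovers_complete_data_effect(self, mcar_trial):
        data, truth = mcar_trial
        res = run_sensitivity(data, [SPSet()], ImputationConfig(m=10, n_cycles=5, seed=7))
        for t in (1, 2):
            complete_beta = fit_effect_model(truth.complete, t).beta
            assert abs(res.table[f"beta_{t}"].iloc[0] - complete_beta) < 0.25

    def test_row_seed_is_position_free(self):
        assert _row_seed(3, SPSet(1.0, -0.5, 1.0, -0.5)) == _row_seed(3, SPSet(1.0, -0.5, 1.0, -0.5))
        assert _row_seed(3, SPSet(1.0, 0.0, 1.0, 0.0)) != _row_seed(3, SPSet(0.0, 1.0, 0.0, 1.0))


class TestBetweenTimeCorrelation:
    def test_duplicated_column_gives_unit_correlation(self):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3})
        r, excluded = between_time_correlation(res, "C")
        assert np.isclose(r, 1.0)  # pi_2C is a positive multiple of pi_1C
        assert excluded == 0

    def test_decreasing_function_gives_minus_one(self):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3})
        res.table["pi_2C"] = 100.0 - res.table["pi_1C"]
        r, _ = between_time_correlation(res, "C")
        assert np.isclose(r, -1.0)

    def test_default_linkage_yields_strong_positive_correlation(self, mnar_trial):
        data, _ = mnar_trial
        grid = build_sp_grid(SPGridConfig(delta_range=(-2, 2), step=2.0))
        res = run_sensitivity(data, grid, ImputationConfig(m=3, n_cycles=5, seed=9))
        for arm in ("C", "E"):
            r, _ = between_time_correlation(res, arm)
            assert r > 0.7

    def test_undefined_rows_excluded_and_counted(self):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3})
        res.table.loc[:4, "pi_2C"] = np.nan
        _, excluded = between_time_correlation(res, "C")
        assert excluded == 5
        with pytest.raises(ValueError):
            between_time_correlation(res, "X")


class TestSurfaces:
    def test_constant_surface_flat_on_hull(self):
        res = _planar_result(lambda pc, pe: {"or": 1.3, "p": 0.4})
        surf = contour_surface(res, 1, "odds_ratio")
        probe = surf(np.column_stack([np.linspace(10, 70, 9), np.linspace(10, 70, 9)]))
        assert np.allclose(probe, 1.3)

    def test_vertex_interpolation_identity(self, mnar_trial):
        data, _ = mnar_trial
        grid = build_sp_grid(SPGridConfig(delta_range=(-1, 1), step=1.0))
        res = run_sensitivity(data, grid, ImputationConfig(m=3, n_cycles=5, seed=10))
        surf = contour_surface(res, 1, "odds_ratio")
        for pt, val in zip(surf.points, surf.values):
            assert np.isclose(surf(pt)[0], val)

    def test_planar_field_contours_are_straight(self):
        res = _planar_result(lambda pc, pe: {"or": 1.0 + 0.01 * (pe - pc), "p": 0.5})
        surf = contour_surface(res, 1, "odds_ratio")
        pts = np.array([[20.0, 30.0], [40.0, 50.0], [55.0, 65.0]])
        assert np.allclose(surf(pts), 1.1)  # level set parallel to identity

    def test_no_extrapolation_outside_hull(self):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3})
        surf = contour_surface(res, 1, "odds_ratio")
        assert np.isnan(surf([90.0, 90.0])[0])

    def test_collinear_scatter_rejected(self):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3})
        res.table["pi_1E"] = res.table["pi_1C"]
        with pytest.raises(ValueError, match="collinear|degenerate"):
            contour_surface(res, 1, "odds_ratio")


class TestSignificanceBoundary:
    def test_planar_p_field_boundary_on_analytic_line(self):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.05 + 0.0025 * (pe - pc)})
        surf = contour_surface(res, 1, "p_value")
        lines = significance_boundary(res, 1, alpha=0.05)
        assert lines
        pts = np.concatenate(lines)
        # the level set p = 0.05 is the identity line pi_E = pi_C
        assert np.allclose(pts[:, 1] - pts[:, 0], 0.0, atol=1.0)
        assert np.nanmax(np.abs(surf(pts) - 0.05)) < 5e-3

    def test_all_insensitive_gives_empty_boundary(self):
        res = _planar_result(lambda pc, pe: {"or": 1.1, "p": 0.4})
        assert significance_boundary(res, 1, alpha=0.05) == []


class TestOverlayReport:
    def test_empty_region_list_produces_plain_report(self, tmp_path):
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3})
        summary = overlay_report(res, out_dir=tmp_path)
        assert summary["times"][1]["regions"] == []
        assert (tmp_path / "sa_time1.png").exists()
        assert (tmp_path / "sa_summary.json").exists()

    def test_insensitive_region_verdict(self, example_prior):
        res = _planar_result(lambda pc, pe: {"or": 1.1, "p": 0.2 + 0.001 * pe})
        samples = sample_prior(example_prior, 20_000, seed=1)
        regions = hdr_contours(samples, coverages=(0.9,))
        summary = overlay_report(res, regions=regions)
        verdict = summary["times"][1]["regions"][0]
        assert verdict["verdict"] == "insensitive"
        assert not verdict["crosses_significance"]
        assert verdict["or_range"][0] >= 1.0

    def test_sensitive_region_detected(self, example_prior):
        # p drops below alpha where the experimental nonresponder rate
        # well exceeds the control rate
        res = _planar_result(lambda pc, pe: {"or": 1.2, "p": 0.3 - 0.012 * (pe - pc)})
        samples = sample_prior(example_prior, 20_000, seed=2)
        regions = hdr_contours(samples, coverages=(0.9,))
        summary = overlay_report(res, regions=regions)
        assert summary["times"][1]["regions"][0]["verdict"] == "sensitive"
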
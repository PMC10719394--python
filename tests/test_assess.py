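"""Change-assessment statistics: windows, normalization, bands, sections."""

import numpy as np
import pytest

from eutroscen.assess import (
    AlignmentError,
    WindowError,
    average_vertical,
    band_stats,
    bightwide_mean,
    considerable_area,
    cross_section,
    integrate_vertical,
    normalized_change,
    weighted_quantile,
)
from eutroscen.grid import Grid


@pytest.fixture
def column_grid():
    """Grid with two layers 0-40 and 40-120 m, deep everywhere."""
    return Grid(
        lon=np.array([-119.0, -118.97]),
        lat=np.array([33.0, 33.03]),
        z_centers=np.array([20.0, 80.0]),
        z_thickness=np.array([40.0, 80.0]),
        bathymetry=np.full((2, 2), 500.0),
        land_mask=np.zeros((2, 2), dtype=bool),
    )


class TestVerticalWindow:
    def test_uniform_rate_integrates_to_rate_times_window(self, simple_grid):
        field = np.full((simple_grid.nz,) + simple_grid.shape, 0.5)
        wet = simple_grid.wet_mask3d()
        field[~wet] = np.nan
        out = integrate_vertical(field, simple_grid, (0.0, 100.0))
        deep = simple_grid.bathymetry >= 100.0
        np.testing.assert_allclose(out[deep & ~simple_grid.land_mask], 50.0)

    def test_zero_field_integrates_to_zero(self, simple_grid):
        field = np.zeros((simple_grid.nz,) + simple_grid.shape)
        out = integrate_vertical(field, simple_grid, (0.0, 100.0))
        np.testing.assert_allclose(out, 0.0)

    def test_piecewise_two_layer_sum(self, column_grid):
        # 1.0 over 0-40 m and 0.25 over 40-100 m -> 40 + 15 = 55
        field = np.empty((2, 2, 2))
        field[0] = 1.0
        field[1] = 0.25
        out = integrate_vertical(field, column_grid, (0.0, 100.0))
        np.testing.assert_allclose(out, 55.0)

    def test_average_is_integral_over_span_on_deep_columns(self, column_grid):
        field = np.empty((2, 2, 2))
        field[0] = 1.0
        field[1] = 0.25
        avg = average_vertical(field, column_grid, (0.0, 100.0))
        integ = integrate_vertical(field, column_grid, (0.0, 100.0))
        np.testing.assert_allclose(avg, integ / 100.0)

    def test_window_below_grid_rejected(self, column_grid):
        field = np.zeros((2, 2, 2))
        with pytest.raises(WindowError):
            integrate_vertical(field, column_grid, (500.0, 600.0))


class TestNormalizedChange:
    def test_scenario_equal_anth_gives_zero(self):
        nc = normalized_change([5.0, 6.0], [5.0, 6.0], [1.0, 2.0])
        assert nc.mean_pct == 0.0
        assert nc.sem_pct == 0.0

    def test_scenario_equal_ctrl_gives_minus_100(self):
        nc = normalized_change([1.0, 2.0], [5.0, 6.0], [1.0, 2.0])
        assert nc.mean_pct == pytest.approx(-100.0)

    def test_two_year_arithmetic(self):
        # per-year values -30 and -40 -> mean -35, SEM 5
        nc = normalized_change([7.0, 6.0], [10.0, 10.0], [0.0, 0.0])
        assert nc.per_year_pct.tolist() == pytest.approx([-30.0, -40.0])
        assert nc.mean_pct == pytest.approx(-35.0)
        assert nc.sem_pct == pytest.approx(5.0)

    def test_single_year_has_no_sem(self):
        nc = normalized_change([7.0], [10.0], [0.0])
        assert nc.sem_pct is None and nc.n_years == 1

    def test_degenerate_denominator_masked(self):
        nc = normalized_change([7.0, 6.0], [10.0, 10.0], [10.0, 0.0])
        assert nc.n_years == 1
        assert nc.per_year_pct[0] != nc.per_year_pct[0]  # NaN


class TestConsiderableArea:
    def test_all_zero_delta_gives_zero_areas(self, simple_grid):
        delta = np.zeros(simple_grid.shape)
        inshore, offshore = considerable_area(delta, simple_grid)
        for b in (inshore, offshore):
            assert b.area_above_km2 == 0.0 and b.area_below_km2 == 0.0

    def test_brute_force_cell_sum(self, simple_grid):
        rng = np.random.default_rng(11)
        delta = rng.uniform(-20, 20, simple_grid.shape)
        delta[simple_grid.land_mask] = np.nan
        inshore, offshore = considerable_area(delta, simple_grid, threshold=10.0, band_km=15.0)
        area = simple_grid.cell_area / 1e6
        ocean = ~simple_grid.land_mask
        inband = ocean & (simple_grid.dist_coast <= 15.0)
        brute_above = area[inband & (delta > 10.0)].sum()
        brute_below_off = area[ocean & ~inband & (delta < -10.0)].sum()
        assert inshore.area_above_km2 == pytest.approx(brute_above)
        assert offshore.area_below_km2 == pytest.approx(brute_below_off)
        # partition: no double counting
        assert inshore.band_area_km2 + offshore.band_area_km2 == pytest.approx(
            area[ocean].sum()
        )

    def test_negating_delta_swaps_above_and_below(self, simple_grid):
        rng = np.random.default_rng(12)
        delta = rng.uniform(-20, 20, simple_grid.shape)
        a_in, a_off = considerable_area(delta, simple_grid)
        b_in, b_off = considerable_area(-delta, simple_grid)
        assert a_in.area_above_km2 == pytest.approx(b_in.area_below_km2)
        assert a_off.area_below_km2 == pytest.approx(b_off.area_above_km2)

    def test_monotone_non_increasing_in_threshold(self, simple_grid):
        rng = np.random.default_rng(13)
        delta = rng.uniform(-30, 30, simple_grid.shape)
        areas = []
        for thr in (5.0, 10.0, 15.0, 20.0):
            inshore, offshore = considerable_area(delta, simple_grid, threshold=thr)
            areas.append(inshore.area_above_km2 + offshore.area_above_km2)
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestBandStats:
    def test_uniform_decline(self, simple_grid):
        delta = np.full(simple_grid.shape, -3.0)
        b = band_stats(delta, simple_grid)
        assert b.mean_decline == pytest.approx(3.0)
        assert b.p95_decline == pytest.approx(3.0)

    def test_equal_area_two_point_quantile(self):
        # equal weights reduce to the standard linear quantile: p95 of {1, 9} = 8.6
        assert weighted_quantile([1.0, 9.0], [2.0, 2.0], 0.95) == pytest.approx(
            np.quantile([1.0, 9.0], 0.95)
        )
        assert np.quantile([1.0, 9.0], 0.95) == pytest.approx(8.6)

    def test_weighted_quantile_matches_numpy_for_equal_weights(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 10, 40)
        w = np.full(40, 2.5)
        for q in (0.05, 0.5, 0.95):
            assert weighted_quantile(vals, w, q) == pytest.approx(np.quantile(vals, q))

    def test_mixed_signs_mean_signed_p95_declines_only(self, simple_grid):
        delta = np.zeros(simple_grid.shape)
        ocean = ~simple_grid.land_mask
        inband = ocean & (simple_grid.dist_coast <= 15.0)
        jj, ii = np.nonzero(inband)
        delta[:, :] = np.nan
        vals = np.linspace(-6, 4, jj.size)  # declines 6 .. increases 4
        delta[jj, ii] = vals
        b = band_stats(delta, simple_grid)
        area = simple_grid.cell_area / 1e6
        signed_mean = np.sum(-vals * area[jj, ii]) / np.sum(area[jj, ii])
        assert b.mean_decline == pytest.approx(signed_mean)
        declines = -vals[vals < 0]
        assert b.p95_decline <= declines.max() + 1e-9
        assert b.p95_decline >= np.quantile(declines, 0.5)

    def test_empty_band_rejected(self, simple_grid):
        delta = np.full(simple_grid.shape, np.nan)
        with pytest.raises(AlignmentError, match="empty"):
            band_stats(delta, simple_grid)


class TestCrossSection:
    def test_function_of_distance_reproduced(self, simple_grid):
        f = lambda d: 2.0 * d + 1.0
        nz = simple_grid.nz
        field = np.broadcast_to(
            f(simple_grid.dist_coast)[None], (nz,) + simple_grid.shape
        ).copy()
        field[~simple_grid.wet_mask3d()] = np.nan
        cs = cross_section(field, simple_grid, bins_km=np.arange(0, 30, 3.0))
        for b in range(cs.section.shape[1]):
            col = cs.section[:, b]
            if np.all(np.isnan(col)):
                continue
            ocean = ~simple_grid.land_mask
            sel = ocean & (np.digitize(simple_grid.dist_coast, np.arange(0, 30, 3.0)) - 1 == b)
            expected = f(simple_grid.dist_coast[sel]).mean()
            assert col[0] == pytest.approx(expected)

    def test_zero_field_zero_section(self, simple_grid):
        field = np.zeros((simple_grid.nz,) + simple_grid.shape)
        field[~simple_grid.wet_mask3d()] = np.nan
        cs = cross_section(field, simple_grid)
        fin = np.isfinite(cs.section)
        assert fin.any()
        np.testing.assert_allclose(cs.section[fin], 0.0)
        np.testing.assert_allclose(cs.profile[np.isfinite(cs.profile)], 0.0)

    def test_random_field_group_by_oracle(self, simple_grid):
        rng = np.random.default_rng(21)
        field = rng.normal(size=(simple_grid.nz,) + simple_grid.shape)
        field[~simple_grid.wet_mask3d()] = np.nan
        bins = np.arange(0, 30, 5.0)
        cs = cross_section(field, simple_grid, bins_km=bins)
        ocean = ~simple_grid.land_mask
        idx = np.digitize(simple_grid.dist_coast, bins) - 1
        for b in range(bins.size - 1):
            sel = ocean & (idx == b)
            if not sel.any():
                assert np.all(np.isnan(cs.section[:, b]))
                continue
            for kz, z in enumerate(cs.z_centers):
                vals = field[kz][sel]
                if np.isfinite(vals).any():
                    assert cs.section[kz, b] == pytest.approx(np.nanmean(vals))


def test_bightwide_mean_area_weighting(simple_grid):
    field = np.where(simple_grid.land_mask, np.nan, 2.0)
    assert bightwide_mean(field, simple_grid) == pytest.approx(2.0)
    assert bightwide_mean(field, simple_grid, area_weighted=False) == pytest.approx(2.0)
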
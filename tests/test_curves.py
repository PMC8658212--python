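import numpy as np
import pytest

from tropref.curves import (
    AxisConfig,
    DEFAULT_AXES,
    floating_stat_curve,
    floating_surface,
    percentile_band,
)
from tropref.errors import DomainError, ValidationError


@pytest.fixture()
def unit_axis():
    return AxisConfig(step=1.0, half_width=5.0, min_window_n=1)


class TestFloatingCurve:
    def test_constant_data(self, unit_axis, rng):
        xs = rng.uniform(0, 50, 300)
        curve = floating_stat_curve(xs, np.full(300, 7.0), unit_axis, "median")
        populated = curve.window_n > 0
        assert np.all(curve.values[populated] == 7.0)

    def test_identity_median_on_uniform_grid(self, unit_axis):
        xs = np.arange(0.0, 101.0)
        curve = floating_stat_curve(xs, xs, unit_axis, "median")
        # symmetric window at interior grid points: median equals the center
        interior = (curve.grid >= 5) & (curve.grid <= 95)
        np.testing.assert_allclose(curve.values[interior], curve.grid[interior])

    def test_empty_window_missing(self):
        cfg = AxisConfig(step=1.0, half_width=0.4, min_window_n=1)
        xs = np.array([0.0, 10.0])
        curve = floating_stat_curve(xs, np.array([1.0, 2.0]), cfg, "median")
        mid = (curve.grid > 0.4) & (curve.grid < 9.6)
        assert np.all(np.isnan(curve.values[mid]))
        assert np.all(curve.window_n[mid] == 0)

    def test_grid_rounded_outward(self):
        cfg = AxisConfig(step=10.0, half_width=15.0, min_window_n=1)
        xs = np.array([12.0, 57.0])
        curve = floating_stat_curve(xs, xs, cfg, "median")
        assert curve.grid[0] == 10.0 and curve.grid[-1] == 60.0

    def test_window_is_closed(self):
        cfg = AxisConfig(step=1.0, half_width=1.0, min_window_n=1)
        xs = np.array([0.0, 1.0, 2.0])
        curve = floating_stat_curve(xs, np.array([5.0, 6.0, 7.0]), cfg, "median")
        at1 = int(np.flatnonzero(curve.grid == 1.0)[0])
        assert curve.window_n[at1] == 3  # both endpoints included

    def test_length_mismatch(self, unit_axis):
        with pytest.raises(ValidationError):
            floating_stat_curve([1, 2], [1], unit_axis, "median")

    def test_shift_equivariance(self, unit_axis, rng):
        xs = rng.uniform(0, 40, 500)
        ys = rng.lognormal(1.0, 0.5, 500)
        base = floating_stat_curve(xs, ys, unit_axis, 99.0)
        shifted = floating_stat_curve(xs, ys + 11.5, unit_axis, 99.0)
        defined = ~np.isnan(base.values)
        np.testing.assert_allclose(
            shifted.values[defined], base.values[defined] + 11.5
        )

    def test_locality(self, unit_axis, rng):
        xs = rng.uniform(0, 60, 400)
        ys = rng.lognormal(1.0, 0.5, 400)
        base = floating_stat_curve(xs, ys, unit_axis, "median")
        ys2 = ys.copy()
        ys2[0] += 1000.0
        pert = floating_stat_curve(xs, ys2, unit_axis, "median")
        far = np.abs(base.grid - xs[0]) > unit_axis.half_width
        both = far & ~np.isnan(base.values)
        np.testing.assert_array_equal(base.values[both], pert.values[both])

    def test_percentile_ordering(self, rng):
        xs = rng.uniform(20, 80, 2000)
        ys = rng.lognormal(1.5, 0.5, 2000)
        cfg = DEFAULT_AXES["age"]
        p50 = floating_stat_curve(xs, ys, cfg, "median")
        p99 = floating_stat_curve(xs, ys, cfg, 99.0)
        both = ~np.isnan(p50.values) & ~np.isnan(p99.values)
        assert np.all(p50.values[both] <= p99.values[both])


class TestPercentileBand:
    def test_constant_data(self, rng):
        xs = rng.uniform(20, 60, 300)
        low, high = percentile_band(xs, np.full(300, 4.2), DEFAULT_AXES["age"])
        for curve in (low, high):
            defined = ~np.isnan(curve.values)
            assert np.all(curve.values[defined] == 4.2)
        assert low.half_width == 10.0  # band uses its own window

    def test_invalid_order(self, rng):
        xs = rng.uniform(0, 10, 50)
        with pytest.raises(ValidationError):
            percentile_band(xs, xs, DEFAULT_AXES["age"], p_low=99.0, p_high=97.0)

    def test_band_brackets_p99(self, rng):
        xs = rng.uniform(20, 80, 3000)
        ys = rng.lognormal(1.5, 0.5, 3000)
        cfg = DEFAULT_AXES["age"]
        low, high = percentile_band(xs, ys, cfg)
        p99 = floating_stat_curve(xs, ys, cfg, 99.0)
        # compare on the band's own windows to keep samples identical
        p99_wide = floating_stat_curve(
            xs, ys, AxisConfig(step=1.0, half_width=10.0), 99.0
        )
        defined = ~np.isnan(p99_wide.values)
        assert np.all(low.values[defined] <= p99_wide.values[defined])
        assert np.all(p99_wide.values[defined] <= high.values[defined])


class TestSurface:
    def test_constant_surface(self, rng):
        n = 2000
        ages = rng.uniform(20, 80, n)
        crs = rng.uniform(50, 110, n)
        surf = floating_surface(ages, crs, np.full(n, 9.0))
        defined = ~np.isnan(surf.values)
        assert defined.any()
        assert np.all(surf.values[defined] == 9.0)

    def test_rows_constant_when_y_depends_on_age_only(self, rng):
        n = 4000
        ages = rng.uniform(20, 80, n)
        crs = rng.uniform(50, 110, n)
        # value constant on every +/-2.4-year window around a 5-year grid node:
        # all subjects inside any age window share one value, so each row of
        # the surface is exactly constant whatever the creatinine slice
        ys = 2.0 + 0.1 * (np.round(ages / 5.0) * 5.0)
        cfg_age = AxisConfig(step=5.0, half_width=2.4, min_window_n=5)
        cfg_cr = AxisConfig(step=10.0, half_width=15.0, min_window_n=5)
        surf = floating_surface(ages, crs, ys, cfg_age, cfg_cr, stat=99.0)
        checked = 0
        for i, g_age in enumerate(surf.age_grid):
            row = surf.values[i]
            defined = ~np.isnan(row)
            if defined.any():
                np.testing.assert_allclose(row[defined], 2.0 + 0.1 * g_age)
                checked += 1
        assert checked > 5

    def test_missing_below_min_window(self, rng):
        ages = np.array([30.0, 31.0])
        crs = np.array([70.0, 71.0])
        surf = floating_surface(ages, crs, np.array([4.0, 5.0]))
        assert np.isnan(surf.values).all()  # min_window_n defaults to 20
        assert surf.window_n.max() == 2

    def test_shape_consistency(self, rng):
        n = 500
        surf = floating_surface(
            rng.uniform(20, 80, n), rng.uniform(40, 120, n),
            rng.lognormal(1.5, 0.4, n),
        )
        assert surf.values.shape == (len(surf.age_grid), len(surf.creatinine_grid))
        assert surf.window_n.shape == surf.values.shape

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            floating_surface([1.0], [1.0, 2.0], [1.0])
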
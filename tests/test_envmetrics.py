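import numpy as np
import pandas as pd
import pytest
import xarray as xr

from ddpop import (
    ColonySite,
    EnvGrid,
    EnvGridSpec,
    climate_temporal_variation,
    haversine_km,
    monthly_aggregate,
    pixels_in_range,
    resource_spatiotemporal_variation,
    simulate_env_grid,
    temporal_sd_per_pixel,
)


def small_grid(values, lat=None, lon=None, year=None, month=None, variable="SST"):
    values = np.asarray(values, dtype=float)
    n_t, n_lat, n_lon = values.shape
    return EnvGrid(
        variable=variable,
        values=values,
        year=np.asarray(year if year is not None else np.repeat(2000 + np.arange(n_t // 1), 1)[:n_t]),
        month=np.asarray(month if month is not None else np.full(n_t, 5)),
        lat=np.asarray(lat if lat is not None else 56 + 0.09 * np.arange(n_lat)),
        lon=np.asarray(lon if lon is not None else -3 + 0.16 * np.arange(n_lon)),
    )


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_km(56.0, -3.0, 56.0, -3.0) == 0.0

    def test_one_degree_latitude(self):
        # 1 degree of latitude ~ 111.2 km on a 6371 km sphere
        d = haversine_km(56.0, -3.0, 57.0, -3.0)
        assert d == pytest.approx(111.19, abs=0.1)

    def test_symmetry(self, rng):
        a = rng.uniform(-80, 80, 4)
        b = rng.uniform(-170, 170, 4)
        d1 = haversine_km(a[0], b[0], a[1], b[1])
        d2 = haversine_km(a[1], b[1], a[0], b[0])
        assert d1 == pytest.approx(d2)


class TestPixelsInRange:
    def test_tiny_radius_on_center_pixel(self):
        grid = small_grid(np.zeros((2, 5, 5)))
        site = ColonySite("c", float(grid.lat[2]), float(grid.lon[2]))
        mask = pixels_in_range(grid, site, radius_km=1.0)
        assert mask.sum() == 1
        assert mask[2, 2]

    def test_plus_shaped_neighbourhood(self):
        # ~1 km grid: a radius between the 4-neighbour distance (1.0 km) and
        # the diagonal distance (1.414 km) catches exactly the plus shape
        lat = 56 + (1.0 / 111.2) * np.arange(5)
        lon = -3 + (1.0 / (111.2 * np.cos(np.deg2rad(56)))) * np.arange(5)
        grid = small_grid(np.zeros((2, 5, 5)), lat=lat, lon=lon)
        site = ColonySite("c", float(lat[2]), float(lon[2]))
        mask = pixels_in_range(grid, site, radius_km=1.2)
        assert mask.sum() == 5
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = expected[1, 2] = expected[3, 2] = expected[2, 1] = expected[2, 3] = True
        np.testing.assert_array_equal(mask, expected)

    def test_radius_spanning_grid(self):
        grid = small_grid(np.zeros((2, 4, 4)))
        site = ColonySite("c", float(grid.lat.mean()), float(grid.lon.mean()))
        mask = pixels_in_range(grid, site, radius_km=10000.0)
        assert mask.all()

    def test_empty_selection_names_colony(self):
        grid = small_grid(np.zeros((2, 4, 4)))
        site = ColonySite("far-away", -55.0, 100.0)
        with pytest.raises(ValueError, match="far-away"):
            pixels_in_range(grid, site, radius_km=5.0)


class TestMonthlyAggregate:
    def _daily(self, values, start="2000-01-01"):
        time = pd.date_range(start, periods=values.shape[0], freq="D")
        return xr.DataArray(
            values,
            dims=("time", "lat", "lon"),
            coords={"time": time, "lat": [56.0, 56.1], "lon": [-3.0, -2.9]},
            name="SSH",
        )

    def test_constant_daily_value(self):
        da = self._daily(np.full((62, 2, 2), 4.2))
        grid = monthly_aggregate(da)
        assert np.allclose(grid.values, 4.2)
        assert list(grid.month[:2]) == [1, 2]

    def test_mean_of_one_to_thirty(self):
        vals = np.arange(1, 31, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        da = self._daily(vals, start="2001-04-01")
        grid = monthly_aggregate(da)
        assert np.allclose(grid.values[0], 15.5)

    def test_leap_february(self):
        vals = np.ones((29, 2, 2), dtype=float)
        vals[-1] = 30.0  # Feb 29 2000 present
        da = self._daily(vals, start="2000-02-01")
        grid = monthly_aggregate(da)
        expected = (28 * 1.0 + 30.0) / 29
        assert np.allclose(grid.values[0], expected)
        assert grid.month[0] == 2


class TestTemporalSD:
    def test_constant_field_zero_sd(self):
        grid = small_grid(np.full((8, 3, 3), 2.0))
        sd = temporal_sd_per_pixel(grid)
        assert np.allclose(sd, 0.0)

    def test_alternating_closed_form(self):
        n = 10
        a = 3.0
        vals = np.empty((n, 2, 2))
        vals[::2] = a
        vals[1::2] = -a
        grid = small_grid(vals)
        sd = temporal_sd_per_pixel(grid)
        expected = a * np.sqrt(n / (n - 1))
        assert np.allclose(sd, expected)

    def test_month_masking(self):
        # months outside 4..7 carry huge values that must be excluded
        months = np.array([4, 5, 6, 7, 12, 12, 4, 5, 6, 7])
        vals = np.ones((10, 2, 2))
        vals[months == 12] = 1e6
        grid = small_grid(vals, month=months, year=np.repeat([2000, 2001], 5))
        sd = temporal_sd_per_pixel(grid, months=(4, 5, 6, 7))
        assert np.allclose(sd, 0.0)


class TestBufferMetrics:
    def test_uniform_sd_field_gives_that_sd(self):
        grid = simulate_env_grid(
            EnvGridSpec(n_lat=6, n_lon=6, temporal_sd_field=0.0, mean_field=1.0, seed=0)
        )
        # overwrite with exact alternating +/-1 anomalies -> known SD
        vals = np.zeros_like(grid.values)
        vals[::2] = 1.0
        vals[1::2] = -1.0
        grid.values = vals
        site = ColonySite("c", float(grid.lat[3]), float(grid.lon[3]))
        m = climate_temporal_variation(grid, site, radius_km=25.0, months=None)
        n_t = grid.values.shape[0]
        assert m.value == pytest.approx(np.sqrt(n_t / (n_t - 1)), rel=1e-12)

    def test_two_pixel_mean(self):
        vals = np.zeros((4, 1, 2))
        vals[:, 0, 0] = [0, 2, 0, 2]  # sd = 1 * sqrt(4/3)... compute exactly below
        vals[:, 0, 1] = [0, 6, 0, 6]
        grid = small_grid(vals)
        sd0 = np.std(vals[:, 0, 0], ddof=1)
        sd1 = np.std(vals[:, 0, 1], ddof=1)
        site = ColonySite("c", float(grid.lat[0]), float(grid.lon.mean()))
        m = climate_temporal_variation(grid, site, radius_km=50.0, months=None)
        assert m.value == pytest.approx((sd0 + sd1) / 2)
        s = resource_spatiotemporal_variation(grid, site, radius_km=50.0, months=None)
        assert s.value == pytest.approx(np.std([sd0, sd1], ddof=1))

    def test_spatial_sd_closed_form_one_three(self):
        # buffer pixel temporal SDs {1, 3} -> spatial SD = sqrt(2)
        assert np.std([1.0, 3.0], ddof=1) == pytest.approx(np.sqrt(2))

    def test_spatially_uniform_sds_give_zero(self):
        grid = simulate_env_grid(
            EnvGridSpec(n_lat=5, n_lon=5, temporal_sd_field=0.0, mean_field=3.0, seed=0)
        )
        site = ColonySite("c", float(grid.lat[2]), float(grid.lon[2]))
        s = resource_spatiotemporal_variation(grid, site, radius_km=30.0, months=None)
        assert s.value == 0.0

    def test_scaling_homogeneity(self):
        grid = simulate_env_grid(
            EnvGridSpec(n_lat=5, n_lon=5, temporal_sd_field=1.0, seed=8, months=(4, 5, 6, 7))
        )
        grid2 = EnvGrid(
            variable=grid.variable,
            values=grid.values.mean(axis=0, keepdims=True)
            + 2.0 * (grid.values - grid.values.mean(axis=0, keepdims=True)),
            year=grid.year,
            month=grid.month,
            lat=grid.lat,
            lon=grid.lon,
        )
        site = ColonySite("c", float(grid.lat[2]), float(grid.lon[2]))
        s1 = resource_spatiotemporal_variation(grid, site, radius_km=30.0)
        s2 = resource_spatiotemporal_variation(grid2, site, radius_km=30.0)
        assert s2.value == pytest.approx(2 * s1.value, rel=1e-9)

    def test_shift_invariance_per_pixel_offsets(self, rng):
        grid = simulate_env_grid(EnvGridSpec(n_lat=4, n_lon=4, temporal_sd_field=1.0, seed=3))
        offsets = rng.normal(0, 50, size=(4, 4))
        shifted = EnvGrid(
            variable=grid.variable,
            values=grid.values + offsets[None, :, :],
            year=grid.year,
            month=grid.month,
            lat=grid.lat,
            lon=grid.lon,
        )
        site = ColonySite("c", float(grid.lat[1]), float(grid.lon[2]))
        m1 = climate_temporal_variation(grid, site, radius_km=40.0)
        m2 = climate_temporal_variation(shifted, site, radius_km=40.0)
        assert m1.value == pytest.approx(m2.value, rel=1e-9)

    def test_order_invariance(self, rng):
        grid = simulate_env_grid(EnvGridSpec(n_lat=4, n_lon=4, temporal_sd_field=1.0, seed=4))
        perm = rng.permutation(grid.values.shape[0])
        shuffled = EnvGrid(
            variable=grid.variable,
            values=grid.values[perm],
            year=grid.year[perm],
            month=grid.month[perm],
            lat=grid.lat,
            lon=grid.lon,
        )
        site = ColonySite("c", float(grid.lat[1]), float(grid.lon[1]))
        m1 = climate_temporal_variation(grid, site, radius_km=40.0)
        m2 = climate_temporal_variation(shuffled, site, radius_km=40.0)
        assert m1.value == pytest.approx(m2.value)

    def test_single_pixel_buffer_spatial_sd_errors(self):
        grid = small_grid(np.zeros((3, 5, 5)))
        site = ColonySite("c", float(grid.lat[2]), float(grid.lon[2]))
        with pytest.raises(ValueError):
            resource_spatiotemporal_variation(grid, site, radius_km=1.0, months=None)

    def test_nan_pixels_excluded(self):
        vals = np.ones((6, 3, 3))
        vals[::2] += 1.0
        vals[:, 0, 0] = np.nan  # a land pixel
        grid = small_grid(vals)
        site = ColonySite("c", float(grid.lat[1]), float(grid.lon[1]))
        m = climate_temporal_variation(grid, site, radius_km=100.0, months=None)
        assert m.n_pixels == 8
        assert np.isfinite(m.value)


class TestNetcdfRoundtrip:
    def test_roundtrip(self, tmp_path):
        grid = simulate_env_grid(EnvGridSpec(n_lat=4, n_lon=5, seed=2))
        path = tmp_path / "grid.nc"
        grid.to_netcdf(path)
        back = EnvGrid.from_netcdf(path)
        np.testing.assert_allclose(back.values, grid.values)
        np.testing.assert_array_equal(back.year, grid.year)
        np.testing.assert_array_equal(back.month, grid.month)
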
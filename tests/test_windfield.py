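"""Wind grids: NetCDF round trip, resampling, sampling rules, summaries."""

import numpy as np
import pandas as pd
import pytest
import shapely
import xarray as xr

from windtrack.geo import GeoPoint
from windtrack.windfield import (
    WindGrid,
    load_wind_grid,
    read_station_csv,
    regional_wind_summary,
    resample_spatial,
    sample_wind,
    sample_wind_arrays,
)

from conftest import make_grid


def _write_nc(path, u, v, levels, times=None, lats=None, lons=None, units="m s**-1"):
    times = times if times is not None else (
        np.datetime64("2012-06-01", "s") + np.arange(u.shape[0]) * np.timedelta64(6, "h")
    )
    lats = lats if lats is not None else np.arange(68.0, 80.0, 0.75)
    lons = lons if lons is not None else np.arange(-180.0, -100.0, 0.75)
    ds = xr.Dataset(
        {
            "u": (("time", "level", "latitude", "longitude"), u, {"units": units}),
            "v": (("time", "level", "latitude", "longitude"), v, {"units": units}),
        },
        coords={"time": times, "level": list(levels), "latitude": lats, "longitude": lons},
    )
    ds.to_netcdf(path, engine="scipy")


def _full(value, n_levels, lats=16, lons=107, n_times=4):
    return np.full((n_times, n_levels, lats, lons), float(value))


def test_load_constant_field_round_trip(tmp_path):
    """A file with constant u=5, v=0 yields (5, 0) at every sample."""
    path = tmp_path / "wind.nc"
    _write_nc(path, _full(5.0, 2), _full(0.0, 2), levels=[0, 925])
    grid = load_wind_grid(path)
    assert grid.levels == ["10m", "750m"]
    w = sample_wind(grid, GeoPoint(-150.0, 72.0), np.datetime64("2012-06-01T07:00"), "750m")
    assert (w.u, w.v) == (5.0, 0.0)
    assert w.speed == 5.0
    assert w.direction_to == pytest.approx(90.0)


def test_load_orders_levels_by_nominal_height(tmp_path):
    path = tmp_path / "wind.nc"
    u = _full(0.0, 3)
    u[:, 0] = 7.0  # 700 hPa (3000 m) listed first in the file
    _write_nc(path, u, _full(0.0, 3), levels=[700, 0, 925])
    grid = load_wind_grid(path)
    assert grid.levels == ["10m", "750m", "3000m"]
    assert grid.u[0, grid.level_index("3000m"), 0, 0] == 7.0
    assert grid.u[0, grid.level_index("10m"), 0, 0] == 0.0


def test_load_errors(tmp_path):
    path = tmp_path / "wind.nc"
    u = _full(1.0, 2)
    u[1, 0, 3, 4] = np.nan
    _write_nc(path, u, _full(0.0, 2), levels=[0, 925])
    with pytest.raises(ValueError, match=r"'u'.*\(1, 0, 3, 4\)"):
        load_wind_grid(path)
    path2 = tmp_path / "wind2.nc"
    _write_nc(path2, _full(1.0, 2), _full(0.0, 2), levels=[0, 333])
    with pytest.raises(ValueError, match="unknown level"):
        load_wind_grid(path2)
    path3 = tmp_path / "wind3.nc"
    ds = xr.Dataset({"u": (("x",), np.arange(3.0))})
    ds.to_netcdf(path3, engine="scipy")
    with pytest.raises(ValueError, match="'v' missing"):
        load_wind_grid(path3)


def test_resample_reproduces_linear_field():
    """Bicubic interpolation reproduces a plane u = 2*lon + 3*lat exactly."""
    grid = make_grid(u=0.0, v=0.0, n_times=2, lats=(70.0, 74.0, 0.72), lons=(-150.0, -144.0, 0.72))
    lon_mesh, lat_mesh = np.meshgrid(grid.lons, grid.lats)
    plane = 2.0 * lon_mesh + 3.0 * lat_mesh
    grid.u[:] = plane
    grid.v[:] = 1.0
    fine = resample_spatial(grid, 10.0)
    lon_f, lat_f = np.meshgrid(fine.lons, fine.lats)
    assert np.allclose(fine.u[0, 0], 2.0 * lon_f + 3.0 * lat_f, atol=1e-6)
    assert np.allclose(fine.v, 1.0, atol=1e-9)


def test_resample_constant_and_precondition():
    grid = make_grid(u=4.0, v=-2.0, n_times=2, lats=(70.0, 74.0, 0.72), lons=(-150.0, -144.0, 0.72))
    fine = resample_spatial(grid, 10.0)
    assert np.allclose(fine.u, 4.0) and np.allclose(fine.v, -2.0)
    with pytest.raises(ValueError, match="not finer"):
        resample_spatial(grid, 160.0)


def test_resampled_constant_grid_samples_agree(constant_grid):
    """Sampling the native and the 10-km-resampled constant grid agree exactly."""
    small = make_grid(u=5.0, v=0.0, n_times=2, lats=(70.0, 74.0, 0.72), lons=(-150.0, -144.0, 0.72))
    fine = resample_spatial(small, 10.0)
    p, t = GeoPoint(-147.3, 71.9), np.datetime64("2012-06-01T03:00")
    assert sample_wind(small, p, t, "10m").u == sample_wind(fine, p, t, "10m").u == 5.0


def test_nearest_time_rule_and_tie():
    grid = make_grid(u=np.array([[1.0, 1.0]] * 1 + [[2.0, 2.0]] * 7), n_times=8)
    p = GeoPoint(-150.0, 72.0)
    # 02:59 is nearer to 00:00 than to 06:00
    assert sample_wind(grid, p, np.datetime64("2012-06-01T02:59"), "10m").u == 1.0
    # exact midpoint 03:00 goes to the earlier slice
    assert sample_wind(grid, p, np.datetime64("2012-06-01T03:00"), "10m").u == 1.0
    assert sample_wind(grid, p, np.datetime64("2012-06-01T03:01"), "10m").u == 2.0


def test_out_of_coverage_errors(constant_grid):
    with pytest.raises(ValueError, match="outside"):
        sample_wind(constant_grid, GeoPoint(-150, 72), np.datetime64("2012-07-15T00:00"), "10m")
    with pytest.raises(ValueError, match="outside"):
        sample_wind(constant_grid, GeoPoint(-50.0, 72.0), np.datetime64("2012-06-01T00:00"), "10m")


def test_linear_time_mode_interpolates(constant_grid):
    grid = make_grid(u=np.array([[0.0, 0.0]] + [[6.0, 6.0]] + [[6.0, 6.0]] * 6), n_times=8)
    u, _ = sample_wind_arrays(
        grid, np.array([-150.0]), np.array([72.0]),
        np.array([np.datetime64("2012-06-01T03:00")]), "10m", time_mode="linear",
    )
    assert u[0] == pytest.approx(3.0)


def test_regional_summary_constant_field(constant_grid):
    region = shapely.box(-160.0, 70.0, -140.0, 78.0)
    out = regional_wind_summary(constant_grid, region, ("2012-06-01", "2012-06-02"))
    assert len(out) == 2
    assert np.allclose(out["mean_speed"], 5.0)
    assert np.allclose(out["mean_direction_to"], 90.0)


def test_regional_summary_degenerate_circular_mean():
    """Opposite winds cancel: speed averages, direction is the NaN sentinel."""
    grid = make_grid(u=0.0, v=0.0, n_times=4, lats=(70.0, 72.1, 0.75), lons=(-150.0, -148.4, 0.75))
    grid.u[:, :, :, 0] = 5.0
    grid.u[:, :, :, 1] = -5.0
    region = shapely.box(-150.4, 69.0, -148.7, 73.0)  # two columns of nodes
    out = regional_wind_summary(grid, region, ("2012-06-01", "2012-06-01"))
    assert out["mean_speed"].iloc[0] == pytest.approx(5.0)
    assert np.isnan(out["mean_direction_to"].iloc[0])


def test_regional_summary_no_overlap_errors(constant_grid):
    with pytest.raises(ValueError, match="overlap"):
        regional_wind_summary(constant_grid, shapely.box(0, 0, 1, 1), ("2012-06-01", "2012-06-01"))


def test_planted_ocean_land_speed_difference():
    """An ocean region planted 1.2 m/s windier recovers the difference."""
    from windtrack.synth import SynthConfig, gen_wind

    cfg = SynthConfig(
        seed=5, temporal_law="ar1", ar1_sigma=1.0, ocean_speed_bonus=1.2, spatial_gradient=0.0
    )
    grid, _ = gen_wind(cfg)
    ocean = shapely.box(-170.0, cfg.coast_lat + 0.4, -110.0, 79.0)
    land = shapely.box(-170.0, 68.2, -110.0, cfg.coast_lat - 0.4)
    dates = ("2012-06-01", "2012-06-10")
    d_ocean = regional_wind_summary(grid, ocean, dates)["mean_speed"]
    d_land = regional_wind_summary(grid, land, dates)["mean_speed"]
    diff = float((d_ocean - d_land).mean())
    assert diff == pytest.approx(1.2, abs=0.05)


def test_station_csv_from_direction_conversion(tmp_path):
    path = tmp_path / "station.csv"
    pd.DataFrame(
        {
            "timestamp": ["2012-06-01T00:00:00", "2012-06-01T01:00:00"],
            "wind_speed_ms": [10.0, 4.0],
            "wind_direction_from_deg": [270.0, 0.0],
        }
    ).to_csv(path, index=False)
    st = read_station_csv(path)
    # wind FROM west (270) blows TOWARD east (90): u = +10
    assert st["u"].iloc[0] == pytest.approx(10.0)
    assert st["v"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert st["direction_to"].iloc[1] == pytest.approx(180.0)
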
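"""Gridded wind fields: loading, resampling, point sampling, summaries.

The in-memory container is :class:`WindGrid`, a regular
(time x level x lat x lon) lattice of eastward (``u``) and northward
(``v``) wind components in m/s, mirroring the layout of a 6-hourly
reanalysis extract with six altitude levels (10 m ground level plus five
pressure levels mapped to nominal heights of 100, 750, 1500, 2250 and
3000 m above sea level).

Sampling along a trajectory is nearest-neighbour in space and time with
ties broken toward the earlier time slice and the lower grid index; no
temporal interpolation is applied by default (an optional linear-in-time
mode exists), because at a 6-h step the wind support seen by a track is
insensitive to +/-6 h shifts (see :func:`temporal_shift_sensitivity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy.interpolate import RectBivariateSpline

from .geo import GeoPoint, normalize_lon

KM_PER_DEG_LAT = 111.195  # pi/180 * 6371 km: one degree of arc on the working sphere

#: Pressure level (hPa) -> nominal height (m a.s.l.). The 10 m ground level
#: is encoded as level value 0 or 10 in files.
DEFAULT_LEVEL_MAP: dict[int, int] = {
    1000: 100,
    925: 750,
    850: 1500,
    775: 2250,
    700: 3000,
}

__all__ = [
    "WindGrid",
    "WindSample",
    "DEFAULT_LEVEL_MAP",
    "load_wind_grid",
    "resample_spatial",
    "sample_wind",
    "sample_wind_arrays",
    "regional_wind_summary",
    "temporal_shift_sensitivity",
    "read_station_csv",
]


@dataclass(frozen=True)
class WindSample:
    """Wind at one point: components, speed and the direction blown *toward*."""

    u: float
    v: float

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))

    @property
    def direction_to(self) -> float:
        """Degrees clockwise from north that the wind blows toward."""
        return float(np.degrees(np.arctan2(self.u, self.v)) % 360.0)


@dataclass
class WindGrid:
    """u/v wind components on a regular (time, level, lat, lon) lattice."""

    times: np.ndarray  # datetime64[s], strictly increasing, equal steps
    levels: list[str]  # names ordered by nominal height, e.g. "10m" ... "3000m"
    heights_m: np.ndarray  # nominal height of each level
    lats: np.ndarray  # ascending, degrees north
    lons: np.ndarray  # ascending, degrees east in [-180, 180)
    u: np.ndarray  # (T, L, Y, X), m/s eastward
    v: np.ndarray  # (T, L, Y, X), m/s northward
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.heights_m = np.asarray(self.heights_m, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        shape = (len(self.times), len(self.levels), len(self.lats), len(self.lons))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v shape {self.u.shape}/{self.v.shape} != {shape}")
        if len(self.times) > 1:
            steps = np.diff(self.times.astype("int64"))
            if not (steps > 0).all():
                raise ValueError("times must be strictly increasing")
            if not (steps == steps[0]).all():
                raise ValueError("times must be equally spaced")
        for name, axis in (("lats", self.lats), ("lons", self.lons)):
            if len(axis) > 1 and not (np.diff(axis) > 0).all():
                raise ValueError(f"{name} must be strictly ascending")
        for var, arr in (("u", self.u), ("v", self.v)):
            if np.isnan(arr).any():
                idx = tuple(int(i[0]) for i in np.nonzero(np.isnan(arr)))
                raise ValueError(f"missing value in variable '{var}' at index {idx}")

    @property
    def time_step(self) -> np.timedelta64:
        if len(self.times) < 2:
            return np.timedelta64(0, "s")
        return self.times[1] - self.times[0]

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"unknown level {level!r}; available: {self.levels}") from None

    def to_dataset(self) -> xr.Dataset:
        """Export as an xarray Dataset (used by the synthetic generator's writer)."""
        return xr.Dataset(
            {
                "u": (("time", "level", "latitude", "longitude"), self.u),
                "v": (("time", "level", "latitude", "longitude"), self.v),
            },
            coords={
                "time": self.times,
                "level": self.heights_m.astype(int),
                "latitude": self.lats,
                "longitude": self.lons,
            },
            attrs={"level_units": "nominal height m a.s.l.", **self.attrs},
        )


def _level_names(heights: np.ndarray) -> list[str]:
    return [f"{int(h)}m" for h in heights]


def load_wind_grid(path, level_map: dict[int, int] | None = None) -> WindGrid:
    """Load a NetCDF wind extract into a :class:`WindGrid`.

    The file must contain variables ``u`` and ``v`` with dimensions
    (time, level, latitude, longitude).  Level coordinate values may be
    pressure levels in hPa (translated through ``level_map``), the
    values 0/10 for the 10 m ground level, or nominal heights directly.
    Levels are reordered by ascending nominal height.  Any missing cell
    is a hard load error naming the variable and index.
    """
    level_map = dict(DEFAULT_LEVEL_MAP if level_map is None else level_map)
    with xr.open_dataset(path, engine="scipy") as ds:
        for var in ("u", "v"):
            if var not in ds:
                raise ValueError(f"variable '{var}' missing from {path}")
        dims = ("time", "level", "latitude", "longitude")
        for d in dims:
            if d not in ds["u"].dims:
                raise ValueError(f"variable 'u' lacks dimension '{d}'")
        units = str(ds["u"].attrs.get("units", "m s**-1"))
        if units not in {"m s**-1", "m s-1", "m/s", "m s^-1"}:
            raise ValueError(f"unexpected wind units {units!r}; expected m/s")

        raw_levels = np.asarray(ds["level"].values)
        heights = []
        known_heights = {10, *level_map.values()}
        for lv in raw_levels:
            lv = int(lv)
            if lv in (0, 10):
                heights.append(10)
            elif lv in level_map:
                heights.append(int(level_map[lv]))
            elif lv in known_heights:
                heights.append(lv)
            else:
                raise ValueError(f"unknown level value {lv} (not in level map)")
        heights = np.asarray(heights, dtype=float)
        order = np.argsort(heights)

        lats = np.asarray(ds["latitude"].values, dtype=float)
        lons = np.array([normalize_lon(x) for x in np.asarray(ds["longitude"].values, float)])
        u = np.asarray(ds["u"].transpose(*dims).values, dtype=float)[:, order]
        v = np.asarray(ds["v"].transpose(*dims).values, dtype=float)[:, order]

        lat_order = np.argsort(lats)
        lon_order = np.argsort(lons)
        times = np.asarray(ds["time"].values)
        time_steps = np.diff(times.astype("datetime64[s]").astype("int64"))
        if len(times) > 1 and not (time_steps == time_steps[0]).all():
            raise ValueError("irregular time axis in wind file")

        return WindGrid(
            times=times,
            levels=_level_names(heights[order]),
            heights_m=heights[order],
            lats=lats[lat_order],
            lons=lons[lon_order],
            u=u[:, :, lat_order][:, :, :, lon_order],
            v=v[:, :, lat_order][:, :, :, lon_order],
        )


def resample_spatial(grid: WindGrid, target_spacing_km: float) -> WindGrid:
    """Bicubic spatial upsampling of ``u`` and ``v`` to a finer grid.

    The interpolant is a bicubic spline fitted independently to every
    time/level slice, which reproduces polynomial fields up to cubic
    order exactly.  Downsampling is refused: the analysis only ever
    refines a coarse reanalysis lattice (nominally ~80 km to 10 km).
    """
    src_km = float(np.diff(grid.lats).mean()) * KM_PER_DEG_LAT
    if target_spacing_km >= src_km:
        raise ValueError(
            f"target spacing {target_spacing_km} km is not finer than source ({src_km:.1f} km)"
        )
    step_deg = target_spacing_km / KM_PER_DEG_LAT
    new_lats = np.arange(grid.lats[0], grid.lats[-1] + 1e-9, step_deg)
    new_lons = np.arange(grid.lons[0], grid.lons[-1] + 1e-9, step_deg)
    kx = min(3, len(grid.lats) - 1)
    ky = min(3, len(grid.lons) - 1)
    T, L = len(grid.times), len(grid.levels)
    out_u = np.empty((T, L, len(new_lats), len(new_lons)))
    out_v = np.empty_like(out_u)
    for ti in range(T):
        for li in range(L):
            for src, dst in ((grid.u, out_u), (grid.v, out_v)):
                spl = RectBivariateSpline(grid.lats, grid.lons, src[ti, li], kx=kx, ky=ky)
                dst[ti, li] = spl(new_lats, new_lons)
    return replace(grid, lats=new_lats, lons=new_lons, u=out_u, v=out_v)


def _nearest_indices(axis: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Nearest index on an ascending axis; exact midpoints go to the lower index."""
    hi = np.searchsorted(axis, values)
    hi = np.clip(hi, 1, len(axis) - 1)
    lo = hi - 1
    # tie (equal distance) -> lower index / earlier slice
    pick_lo = (values - axis[lo]) <= (axis[hi] - values)
    return np.where(pick_lo, lo, hi)


def _check_coverage(grid: WindGrid, lons, lats, times) -> None:
    t = np.asarray(times, dtype="datetime64[s]").astype("int64")
    t0, t1 = grid.times[0].astype("int64"), grid.times[-1].astype("int64")
    slack = int(grid.time_step / np.timedelta64(1, "s"))
    if (t < t0 - slack).any() or (t > t1 + slack).any():
        raise ValueError("query time outside wind grid coverage (span +/- one step)")
    if (
        (np.asarray(lats) < grid.lats[0]).any()
        or (np.asarray(lats) > grid.lats[-1]).any()
        or (np.asarray(lons) < grid.lons[0]).any()
        or (np.asarray(lons) > grid.lons[-1]).any()
    ):
        raise ValueError("query point outside wind grid spatial extent")


def sample_wind_arrays(
    grid: WindGrid,
    lons: np.ndarray,
    lats: np.ndarray,
    times: np.ndarray,
    level: str,
    time_mode: str = "nearest",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized wind sampling: (u, v) at each (lon, lat, time) triple.

    ``time_mode`` is ``"nearest"`` (default; earlier slice wins ties) or
    ``"linear"`` for linear interpolation between the bracketing slices.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    tsec = np.asarray(times, dtype="datetime64[s]").astype("int64")
    _check_coverage(grid, lons, lats, tsec.astype("datetime64[s]"))
    li = grid.level_index(level)
    yi = _nearest_indices(grid.lats, lats)
    xi = _nearest_indices(grid.lons, lons)
    taxis = grid.times.astype("int64")
    if time_mode == "nearest":
        ti = _nearest_indices(taxis, tsec)
        return grid.u[ti, li, yi, xi], grid.v[ti, li, yi, xi]
    if time_mode == "linear":
        hi = np.clip(np.searchsorted(taxis, tsec), 1, len(taxis) - 1)
        lo = hi - 1
        w = np.clip((tsec - taxis[lo]) / (taxis[hi] - taxis[lo]), 0.0, 1.0)
        u = (1 - w) * grid.u[lo, li, yi, xi] + w * grid.u[hi, li, yi, xi]
        v = (1 - w) * grid.v[lo, li, yi, xi] + w * grid.v[hi, li, yi, xi]
        return u, v
    raise ValueError(f"unknown time_mode {time_mode!r}")


def sample_wind(
    grid: WindGrid, p: GeoPoint, t, level: str, time_mode: str = "nearest"
) -> WindSample:
    """Wind at one point/time/level, nearest in space and time by default."""
    u, v = sample_wind_arrays(
        grid, np.array([p.lon]), np.array([p.lat]), np.array([t], dtype="datetime64[s]"),
        level, time_mode=time_mode,
    )
    return WindSample(u=float(u[0]), v=float(v[0]))


def regional_wind_summary(
    grid: WindGrid,
    region: shapely.Polygon,
    dates: tuple,
    level: str = "10m",
) -> pd.DataFrame:
    """Daily mean wind speed and vector-mean direction over a polygon.

    Per calendar day, the mean of the scalar speed over all in-polygon
    nodes and time slices, and the circular (vector) mean direction,
    i.e. ``atan2`` of the component means.  A day with a vanishing
    resultant vector gets a NaN direction sentinel.
    """
    lon_mesh, lat_mesh = np.meshgrid(grid.lons, grid.lats)
    inside = shapely.contains_xy(region, lon_mesh.ravel(), lat_mesh.ravel()).reshape(
        lon_mesh.shape
    )
    if not inside.any():
        raise ValueError("region polygon does not overlap the wind grid")
    li = grid.level_index(level)
    d0 = np.datetime64(pd.Timestamp(dates[0]).date())
    d1 = np.datetime64(pd.Timestamp(dates[1]).date())
    days = grid.times.astype("datetime64[D]")
    rows = []
    for day in np.arange(d0, d1 + np.timedelta64(1, "D")):
        sel = days == day
        if not sel.any():
            continue
        u = grid.u[sel, li][:, inside]
        v = grid.v[sel, li][:, inside]
        mean_u, mean_v = u.mean(), v.mean()
        resultant = float(np.hypot(mean_u, mean_v))
        direction = (
            float(np.degrees(np.arctan2(mean_u, mean_v)) % 360.0) if resultant > 1e-9 else np.nan
        )
        rows.append(
            {
                "date": pd.Timestamp(day),
                "mean_speed": float(np.hypot(u, v).mean()),
                "mean_direction_to": direction,
                "n_nodes": int(inside.sum()),
            }
        )
    return pd.DataFrame(rows)


def temporal_shift_sensitivity(
    tracks, grid: WindGrid, shift_hours: float = 6.0
) -> pd.DataFrame:
    """Correlation of per-track mean wind support, time-shifted vs. observed.

    Every track is rigidly shifted by +/-``shift_hours`` and its mean
    wind support recomputed at every level; the returned frame has one
    Pearson r per (level, shift sign).  High r across levels means the
    grid's native time step resolves the wind the tracks experienced.
    """
    from .windvec import annotate_track  # local import: windvec builds on this module

    if len(tracks) < 3:
        raise ValueError("need at least 3 tracks for a correlation")
    rows = []
    shifts = {
        f"+{shift_hours:g}h": np.timedelta64(int(shift_hours * 3600), "s"),
        f"-{shift_hours:g}h": -np.timedelta64(int(shift_hours * 3600), "s"),
    }
    for level in grid.levels:
        observed = np.array(
            [annotate_track(t, grid, level)["wind_support"].mean() for t in tracks]
        )
        for label, delta in shifts.items():
            shifted = np.array(
                [
                    annotate_track(t.shifted(delta), grid, level)["wind_support"].mean()
                    for t in tracks
                ]
            )
            if np.std(observed) == 0 or np.std(shifted) == 0:
                r = 1.0 if np.allclose(observed, shifted) else np.nan
            else:
                r = float(np.corrcoef(observed, shifted)[0, 1])
            rows.append({"level": level, "shift": label, "pearson_r": r, "n": len(tracks)})
    return pd.DataFrame(rows)


def read_station_csv(path) -> pd.DataFrame:
    """Read an hourly ground-station wind series.

    Expects columns ``timestamp``, ``wind_speed_ms`` and
    ``wind_direction_from_deg`` (meteorological convention: direction the
    wind blows *from*).  Returns a frame indexed by UTC timestamp with
    ``u``, ``v``, ``speed`` and ``direction_to`` columns.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "wind_speed_ms", "wind_direction_from_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    direction_to = ((df["wind_direction_from_deg"] + 180.0) % 360.0).to_numpy(float)
    speed = df["wind_speed_ms"].to_numpy(float)
    rad = np.radians(direction_to)
    out = pd.DataFrame(
        {
            "u": speed * np.sin(rad),
            "v": speed * np.cos(rad),
            "speed": speed,
            "direction_to": direction_to,
        },
        index=pd.DatetimeIndex(df["timestamp"], name="timestamp"),
    )
    return out.sort_index()
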
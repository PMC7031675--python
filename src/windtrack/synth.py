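"""Synthetic worlds: wind grids, station series, coastlines and
wind-coupled tracks with a planted-truth manifest.

The generator emulates the statistical structure of the study system —
an Arctic coastal departure site, a 6-hourly multi-level wind field over
an ocean band, 15-min resolved over-sea flights whose ground vector is
the bird's air vector plus the wind vector — with every latent quantity
recorded, so each pipeline stage can be tested against known truth
without any real download.

Defaults describe one realistic season: a 68-80 degN, 0.75-degree grid
over three weeks at a 6-h step; six altitude levels with mean winds of a
few m/s and temporally autocorrelated anomalies; ~20 tracks departing
around 71.3 degN with an 11 m/s mean air speed and 8-16 h flight
durations, i.e. ground speeds and track lengths in the range reported
for free-flying shorebirds.

Movement kinematics per 15-min step::

    displacement = (air_speed * heading_unit_vector + wind_vector) * 900 s

so with calm crosswind the annotated ground speed recovers
``air_speed + wind_support`` exactly, which is the planted truth the
speed models are tested against.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import geo
from .geo import GeoPoint
from .tracks import Track
from .windfield import WindGrid, sample_wind_arrays

__all__ = [
    "SynthConfig",
    "TruthManifest",
    "gen_wind",
    "gen_tracks",
    "gen_coastline",
    "gen_speed_segments",
    "gen_track_length_data",
    "write_world",
]

STEP_S = 900  # 15-min track step

LEVEL_HEIGHTS = (10, 100, 750, 1500, 2250, 3000)


@dataclass
class SynthConfig:
    """Parameters of a synthetic world.  All randomness flows from ``seed``;
    per-track substreams are derived by stable hashing of the track id."""

    seed: int = 0
    # wind grid
    lon_range: tuple = (-180.0, -100.0)
    lat_range: tuple = (58.0, 84.0)
    spacing_deg: float = 0.75
    t_start: str = "2012-05-30"
    t_end: str = "2012-06-20"
    step_h: int = 6
    level_heights: tuple = LEVEL_HEIGHTS
    #: per-level mean (u, v) in m/s; one pair broadcast to all levels is allowed
    level_mean_wind: tuple = ((2.0, 0.5),) * 6
    temporal_law: str = "ar1"  # "constant" | "sine24" | "ar1"
    sine_amplitude: float = 4.0  # m/s, applied to u with a 24-h period
    sine_phase_h: float = 0.0
    ar1_sigma: float = 2.5  # stationary s.d. of the AR(1) anomaly, m/s
    ar1_tau_h: float = 24.0  # correlation time of the anomaly
    level_decorrelate: bool = True  # independent anomaly stream per level
    spatial_gradient: float = 0.02  # (m/s) per degree, weak smooth spatial structure
    ocean_speed_bonus: float = 0.0  # planted extra wind speed (m/s) over the ocean
    coast_lat: float = 70.0  # land below, ocean above
    station_lon: float = -140.0
    station_lat: float = 71.3
    # tracks
    n_tracks: int = 20
    origin_lon: float = -140.0
    origin_lat: float = 71.3
    departure_jitter_km: float = 30.0
    departure_law: str = "uniform"  # "uniform" | "tailwind_peak"
    air_speed_mean: float = 11.0  # m/s
    air_speed_sd: float = 1.0
    heading_law: str = "downwind"  # "downwind" | "fixed_bearing" | "fixed_goal"
    kappa: float = 8.0  # von Mises concentration of the downwind heading
    east_fraction: float = 0.5  # fixed_bearing law: share of eastbound tracks
    bearing_jitter_sd: float = 12.0  # deg, fixed_bearing law
    goal_lon: float = -120.0
    goal_lat: float = 72.5
    duration_h_range: tuple = (8.0, 16.0)
    loop_fraction: float = 0.0
    active_level: str = "750m"  # the level whose wind actually moves the birds

    def level_names(self) -> list[str]:
        return [f"{int(h)}m" for h in self.level_heights]


@dataclass
class TruthManifest:
    """Everything needed to recompute the planted effects without
    re-running the generator."""

    config: SynthConfig
    active_level: str
    #: planted speed-model truth: ground = air_speed_mean + 1.0 * Ws at zero crosswind
    speed_intercept: float
    speed_ws_coef: float
    per_track: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "active_level": self.active_level,
            "speed_intercept": self.speed_intercept,
            "speed_ws_coef": self.speed_ws_coef,
            "per_track": {
                tid: {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in rec.items()
                }
                for tid, rec in self.per_track.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _track_rng(cfg: SynthConfig, track_id: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, zlib.crc32(track_id.encode())])


def _temporal_anomaly(cfg: SynthConfig, n_hours: int, rng: np.random.Generator) -> np.ndarray:
    """Hourly (level, hour, 2) anomaly added to the mean wind."""
    L = len(cfg.level_heights)
    out = np.zeros((L, n_hours, 2))
    if cfg.temporal_law == "constant":
        return out
    if cfg.temporal_law == "sine24":
        h = np.arange(n_hours, dtype=float)
        out[:, :, 0] = cfg.sine_amplitude * np.sin(
            2.0 * np.pi * (h - cfg.sine_phase_h) / 24.0
        )
        return out
    if cfg.temporal_law == "ar1":
        phi = np.exp(-1.0 / cfg.ar1_tau_h)
        innov_sd = cfg.ar1_sigma * np.sqrt(1.0 - phi**2)
        n_streams = L if cfg.level_decorrelate else 1
        x = np.zeros((n_streams, n_hours, 2))
        x[:, 0] = rng.normal(0.0, cfg.ar1_sigma, size=(n_streams, 2))
        eps = rng.normal(0.0, innov_sd, size=(n_streams, n_hours, 2))
        for t in range(1, n_hours):
            x[:, t] = phi * x[:, t - 1] + eps[:, t]
        out[:] = x if cfg.level_decorrelate else x[0][None, :, :]
        return out
    raise ValueError(f"unknown temporal_law {cfg.temporal_law!r}")


def gen_wind(cfg: SynthConfig) -> tuple[WindGrid, pd.DataFrame]:
    """Generate the gridded wind field and the hourly ground-station series.

    The field is a per-level mean vector plus a weak linear spatial
    gradient and a temporally autocorrelated (or sinusoidal) anomaly
    generated at hourly resolution; the grid keeps every ``step_h``-th
    hour while the station (the 10 m level sampled at the station
    coordinates) keeps the full hourly series, mimicking a reanalysis
    extract alongside a weather-station record.
    """
    t0 = np.datetime64(cfg.t_start, "s")
    t1 = np.datetime64(cfg.t_end, "s") + np.timedelta64(86_400 - cfg.step_h * 3600, "s")
    n_hours = int((t1 - t0).astype("int64") // 3600) + 1
    if n_hours < 1:
        raise ValueError("empty time span")
    lats = np.arange(cfg.lat_range[0], cfg.lat_range[1] + 1e-9, cfg.spacing_deg)
    lons = np.arange(cfg.lon_range[0], cfg.lon_range[1] + 1e-9, cfg.spacing_deg)
    if len(lats) < 2 or len(lons) < 2:
        raise ValueError("zero-size grid")
    rng = np.random.default_rng([cfg.seed, 193939])
    anomaly = _temporal_anomaly(cfg, n_hours, rng)

    means = np.asarray(cfg.level_mean_wind, dtype=float)
    if means.shape == (2,):
        means = np.tile(means, (len(cfg.level_heights), 1))
    if means.shape != (len(cfg.level_heights), 2):
        raise ValueError("level_mean_wind must give one (u, v) pair per level")

    lat_c = float(np.mean(cfg.lat_range))
    lon_c = float(np.mean(cfg.lon_range))
    glat = cfg.spatial_gradient * (lats - lat_c)  # (Y,)
    glon = cfg.spatial_gradient * (lons - lon_c)  # (X,)

    hour_idx = np.arange(0, n_hours, cfg.step_h)
    times = t0 + hour_idx.astype("timedelta64[h]").astype("timedelta64[s]")
    T, L, Y, X = len(times), len(cfg.level_heights), len(lats), len(lons)
    u = np.empty((T, L, Y, X))
    v = np.empty((T, L, Y, X))
    for li in range(L):
        u[:, li] = (
            means[li, 0]
            + anomaly[li, hour_idx, 0][:, None, None]
            + glat[None, :, None]
            + np.zeros((1, 1, X))
        )
        v[:, li] = (
            means[li, 1]
            + anomaly[li, hour_idx, 1][:, None, None]
            + glon[None, None, :]
            + np.zeros((1, Y, 1))
        )
    if cfg.ocean_speed_bonus != 0.0:
        ocean = lats >= cfg.coast_lat
        spd = np.hypot(u[:, :, ocean, :], v[:, :, ocean, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(spd > 0, (spd + cfg.ocean_speed_bonus) / spd, 1.0)
        u[:, :, ocean, :] *= scale
        v[:, :, ocean, :] *= scale

    grid = WindGrid(
        times=times,
        levels=cfg.level_names(),
        heights_m=np.asarray(cfg.level_heights, float),
        lats=lats,
        lons=lons,
        u=u,
        v=v,
        attrs={"synthetic": "true", "seed": cfg.seed},
    )

    # hourly station series: ground level at the station coordinates
    st_lat_g = cfg.spatial_gradient * (cfg.station_lat - lat_c)
    st_lon_g = cfg.spatial_gradient * (cfg.station_lon - lon_c)
    su = means[0, 0] + anomaly[0, :, 0] + st_lat_g
    sv = means[0, 1] + anomaly[0, :, 1] + st_lon_g
    if cfg.ocean_speed_bonus != 0.0 and cfg.station_lat >= cfg.coast_lat:
        spd = np.hypot(su, sv)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(spd > 0, (spd + cfg.ocean_speed_bonus) / spd, 1.0)
        su, sv = su * scale, sv * scale
    st_times = pd.DatetimeIndex(t0 + np.arange(n_hours).astype("timedelta64[h]"), name="timestamp")
    station = pd.DataFrame(
        {
            "u": su,
            "v": sv,
            "speed": np.hypot(su, sv),
            "direction_to": np.degrees(np.arctan2(su, sv)) % 360.0,
        },
        index=st_times,
    )
    return grid, station


def gen_coastline(cfg: SynthConfig) -> shapely.Polygon:
    """The synthetic land mass: everything south of ``coast_lat``."""
    return shapely.box(cfg.lon_range[0] - 1, -90.0, cfg.lon_range[1] + 1, cfg.coast_lat)


def _von_mises_deg(rng, mu_deg: float, kappa: float) -> float:
    return float(np.degrees(rng.vonmises(np.radians(mu_deg), kappa)) % 360.0)


def _departure_time(
    cfg: SynthConfig, rng, grid: WindGrid, dep: GeoPoint, heading: float
) -> np.datetime64:
    w0 = grid.times[0].astype("datetime64[s]")
    w1 = grid.times[-1].astype("datetime64[s]")
    # loops may run up to twice the drawn duration (outbound + return)
    margin = np.timedelta64(2 * int(max(cfg.duration_h_range) * 3600) + 7200, "s")
    span = ((w1 - margin) - w0).astype("int64")
    if span <= 0:
        raise ValueError("wind grid too short for the configured flight durations")
    if cfg.departure_law == "uniform":
        return w0 + np.timedelta64(int(rng.uniform(0, span)), "s")
    if cfg.departure_law == "tailwind_peak":
        # pick a night, then the 15-min slot in it maximizing the coming
        # hour's wind support at the departure point for this heading
        n_days = max(int(span // 86_400), 1)
        day = int(rng.integers(0, n_days))
        slots = w0 + np.timedelta64(day, "D") + (
            np.arange(0, 96) * np.timedelta64(STEP_S, "s")
        )
        sin_h, cos_h = np.sin(np.radians(heading)), np.cos(np.radians(heading))
        best, best_ws = slots[0], -np.inf
        for s in slots:
            qt = s + np.arange(4) * np.timedelta64(STEP_S, "s")
            u, w = sample_wind_arrays(
                grid, np.full(4, dep.lon), np.full(4, dep.lat), qt, cfg.active_level
            )
            ws = float((u * sin_h + w * cos_h).mean())
            if ws > best_ws:
                best, best_ws = s, ws
        return best.astype("datetime64[s]")
    raise ValueError(f"unknown departure_law {cfg.departure_law!r}")


def _simulate_track(
    cfg: SynthConfig, rng, grid: WindGrid, track_id: str
) -> tuple[Track, dict]:
    origin = GeoPoint(cfg.origin_lon, cfg.origin_lat)
    jitter_b = rng.uniform(0, 360)
    jitter_d = rng.uniform(0, cfg.departure_jitter_km * 1000)
    dep = geo.destination_point(origin, jitter_b, jitter_d)
    if dep.lat < cfg.coast_lat:
        dep = GeoPoint(dep.lon, cfg.coast_lat + 0.2)

    is_loop = rng.uniform() < cfg.loop_fraction

    def draw_heading(t_probe) -> float:
        if cfg.heading_law == "fixed_bearing":
            base = 90.0 if rng.uniform() < cfg.east_fraction else 270.0
            return (base + rng.normal(0, cfg.bearing_jitter_sd)) % 360.0
        if cfg.heading_law == "downwind":
            u, v = sample_wind_arrays(
                grid, np.array([dep.lon]), np.array([dep.lat]),
                np.array([t_probe], dtype="datetime64[s]"), cfg.active_level,
            )
            wind_dir = float(np.degrees(np.arctan2(u[0], v[0])) % 360.0)
            return _von_mises_deg(rng, wind_dir, cfg.kappa)
        if cfg.heading_law == "fixed_goal":
            b = geo.initial_bearing_deg(dep, GeoPoint(cfg.goal_lon, cfg.goal_lat))
            return b if b is not None else 90.0
        raise ValueError(f"unknown heading_law {cfg.heading_law!r}")

    if cfg.departure_law == "uniform":
        # heading responds to the wind the bird actually sees at departure
        t_dep = _departure_time(cfg, rng, grid, dep, heading=None)
        heading0 = draw_heading(t_dep)
    else:
        heading0 = draw_heading(grid.times[len(grid.times) // 2].astype("datetime64[s]"))
        t_dep = _departure_time(cfg, rng, grid, dep, heading0)
    duration_h = rng.uniform(*cfg.duration_h_range)
    n_steps = int(duration_h * 3600 / STEP_S)
    # loops: outbound leg, then a goal-seeking return with generous time
    out_steps = int(n_steps * 0.35) if is_loop else n_steps
    if is_loop:
        n_steps = int(n_steps * 2.0)
    loop_goal = geo.destination_point(dep, (heading0 + 90.0) % 360.0, 60_000.0)

    lons = [dep.lon]
    lats = [dep.lat]
    times = [t_dep]
    headings, air_speeds, wind_u, wind_v = [], [], [], []
    pos, t = dep, t_dep
    step = 0
    while step < n_steps:
        if is_loop and step >= out_steps:
            b = geo.initial_bearing_deg(pos, loop_goal)
            if b is None or geo.distance_m(pos, loop_goal) < 15_000.0:
                break
            heading = b
        elif cfg.heading_law == "fixed_goal":
            b = geo.initial_bearing_deg(pos, GeoPoint(cfg.goal_lon, cfg.goal_lat))
            heading = b if b is not None else heading0
        else:
            heading = heading0
        u, v = sample_wind_arrays(
            grid, np.array([pos.lon]), np.array([pos.lat]),
            np.array([t], dtype="datetime64[s]"), cfg.active_level,
        )
        s = max(rng.normal(cfg.air_speed_mean, cfg.air_speed_sd), 0.1)
        dx = (s * np.sin(np.radians(heading)) + u[0]) * STEP_S
        dy = (s * np.cos(np.radians(heading)) + v[0]) * STEP_S
        dist = float(np.hypot(dx, dy))
        brg = float(np.degrees(np.arctan2(dx, dy)) % 360.0)
        new_pos = geo.destination_point(pos, brg, dist) if dist > 0 else pos
        if not (
            grid.lons[0] + 0.5 <= new_pos.lon <= grid.lons[-1] - 0.5
            and grid.lats[0] + 0.5 <= new_pos.lat <= grid.lats[-1] - 0.5
        ):
            raise ValueError(
                f"track {track_id!r} would leave wind coverage at step {step}; "
                "shorten durations or widen the grid"
            )
        headings.append(heading)
        air_speeds.append(s)
        wind_u.append(float(u[0]))
        wind_v.append(float(v[0]))
        pos = new_pos
        t = t + np.timedelta64(STEP_S, "s")
        lons.append(pos.lon)
        lats.append(pos.lat)
        times.append(t)
        step += 1

    cls = "loop" if is_loop else ("directed-east" if np.sin(np.radians(heading0)) > 0 else "directed-west")
    track = Track(
        id=track_id,
        season=int(pd.Timestamp(t_dep).year),
        times=np.array(times, dtype="datetime64[s]"),
        lons=np.array(lons),
        lats=np.array(lats),
        ocean=np.array(lats) >= cfg.coast_lat,
    )
    truth = {
        "class": cls,
        "departure_time": str(pd.Timestamp(t_dep)),
        "heading0": heading0,
        "headings": np.array(headings),
        "air_speeds": np.array(air_speeds),
        "wind_u": np.array(wind_u),
        "wind_v": np.array(wind_v),
    }
    return track, truth


def gen_tracks(cfg: SynthConfig, grid: WindGrid) -> tuple[list[Track], TruthManifest]:
    """Generate wind-coupled tracks and the truth manifest.

    Each 15-min displacement is the air vector (heading from the
    configured law, speed from a truncated normal) plus the wind vector
    sampled from the grid at the ``active_level`` — the same
    nearest-in-space-and-time rule the annotation uses, so planted and
    recovered wind agree exactly.
    """
    manifest = TruthManifest(
        config=cfg,
        active_level=cfg.active_level,
        speed_intercept=cfg.air_speed_mean,
        speed_ws_coef=1.0,
    )
    tracks = []
    for i in range(cfg.n_tracks):
        tid = f"synth{i:03d}"
        rng = _track_rng(cfg, tid)
        track, truth = _simulate_track(cfg, rng, grid, tid)
        tracks.append(track)
        manifest.per_track[tid] = truth
    return tracks, manifest


def gen_speed_segments(
    n_segments: int = 2000,
    n_tracks: int = 20,
    intercept: float = 12.0,
    ws_coef: float = 0.8,
    cw_coef: float = 0.0,
    interaction_coef: float = 0.0,
    sigma: float = 0.5,
    ws_sd: float = 4.0,
    cw_scale: float = 0.0,
    track_effect_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted-truth segment table for speed-model recovery tests.

    ``ground_speed = intercept + ws_coef*Ws + cw_coef*Cw +
    interaction_coef*Ws*Cw + track_effect + noise(sigma)``, with Ws
    normal and Cw half-normal (``cw_scale=0`` plants a calm-crosswind
    world with a tiny jitter to keep the design full rank).
    """
    rng = np.random.default_rng(seed)
    tid = np.repeat([f"t{i:03d}" for i in range(n_tracks)], int(np.ceil(n_segments / n_tracks)))[
        :n_segments
    ]
    ws = rng.normal(0.0, ws_sd, n_segments)
    cw = np.abs(rng.normal(0.0, cw_scale if cw_scale > 0 else 0.05, n_segments))
    effects = dict(
        zip(np.unique(tid), rng.normal(0.0, track_effect_sd, n_tracks))
    )
    y = (
        intercept
        + ws_coef * ws
        + cw_coef * cw
        + interaction_coef * ws * cw
        + np.array([effects[t] for t in tid])
        + rng.normal(0.0, sigma, n_segments)
    )
    df = pd.DataFrame(
        {
            "track_id": tid,
            "ground_speed": y,
            "air_speed": y - ws,
            "wind_support": ws,
            "crosswind": cw,
            "level": "750m",
        }
    )
    df["cum_length_km"] = df.groupby("track_id").cumcount() * 15.0 + 15.0
    return df


def gen_track_length_data(
    n_tracks: int = 80,
    slope: float = 22.0,
    sigma: float = 50.0,
    ws_sd: float = 4.0,
    base_length_km: float = 1360.0,
    class_shifts: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Planted track-length regression world.

    Track length (km) = class intercept + ``slope`` x mean first-half
    wind support (m/s) + Gaussian noise of s.d. ``sigma`` km.  Returns
    the per-track frame and the analytic slope standard error
    ``sigma / (sd(Ws) * sqrt(n))`` used by recovery tests.
    """
    rng = np.random.default_rng(seed)
    class_shifts = class_shifts or {"directed-east": 0.0, "directed-west": 150.0}
    classes = rng.choice(sorted(class_shifts), size=n_tracks)
    ws = rng.normal(0.0, ws_sd, n_tracks)
    length = (
        base_length_km
        + np.array([class_shifts[c] for c in classes])
        + slope * ws
        + rng.normal(0.0, sigma, n_tracks)
    )
    df = pd.DataFrame(
        {
            "track_id": [f"t{i:03d}" for i in range(n_tracks)],
            "track_length_km": length,
            "mean_first_half_ws": ws,
            "flight_class": classes,
        }
    )
    analytic_se = sigma / (np.std(ws, ddof=0) * np.sqrt(n_tracks))
    return df, {"slope": slope, "analytic_se": float(analytic_se)}


def write_world(cfg: SynthConfig, out_dir) -> dict:
    """Generate a full world and write it as plain files.

    Writes ``tracks.csv``, ``wind.nc``, ``station.csv``,
    ``coast.geojson`` and ``manifest.json`` under ``out_dir``; returns
    the paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid, station = gen_wind(cfg)
    tracks, manifest = gen_tracks(cfg, grid)

    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append(
                {
                    "id": t.id,
                    "timestamp": pd.Timestamp(t.times[i]).isoformat(),
                    "lon": t.lons[i],
                    "lat": t.lats[i],
                    "surface": "ocean" if (t.ocean is None or t.ocean[i]) else "land",
                }
            )
    pd.DataFrame(rows).to_csv(out / "tracks.csv", index=False)

    grid.to_dataset().to_netcdf(out / "wind.nc", engine="scipy")

    st = station.reset_index()
    pd.DataFrame(
        {
            "timestamp": st["timestamp"],
            "wind_speed_ms": st["speed"],
            "wind_direction_from_deg": (st["direction_to"] + 180.0) % 360.0,
        }
    ).to_csv(out / "station.csv", index=False)

    coast = gen_coastline(cfg)
    with open(out / "coast.geojson", "w") as fh:
        json.dump(shapely.geometry.mapping(coast), fh)

    manifest.to_json(out / "manifest.json")
    return {
        "tracks": out / "tracks.csv",
        "wind": out / "wind.nc",
        "station": out / "station.csv",
        "coast": out / "coast.geojson",
        "manifest": out / "manifest.json",
    }
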
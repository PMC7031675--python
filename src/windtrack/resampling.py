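"""Null models for departure timing.

Three analyses ask whether birds timed and directed their departures by
the wind rather than by chance:

* :func:`random_departures` shifts a track rigidly in time to random
  departures within the season window and compares the observed mean
  wind support with the simulated ensemble (one-sided exceedance);
* :func:`delta_wind_support` contrasts the support a bird would have had
  flying west versus east from the departure site on a given night;
* :func:`departure_shift_profile` recomputes support toward the actual
  destination at departure +/-12 h (hourly, station wind) and +/-5 days
  (daily, gridded wind), probing whether birds waited for better winds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .geo import GeoPoint
from .tracks import Track
from .windfield import WindGrid, sample_wind, sample_wind_arrays
from .windvec import annotate_track, wind_components

__all__ = [
    "NullDistribution",
    "DeltaWind",
    "ShiftProfile",
    "random_departures",
    "delta_wind_support",
    "departure_shift_profile",
]


@dataclass
class NullDistribution:
    """Observed wind-support statistic vs. a random-departure ensemble."""

    track_id: str
    statistic: str  # "first50" or "full"
    level: str
    observed: float
    simulated: np.ndarray
    p: float  # fraction of simulated >= observed (ties count against significance)
    significant: bool  # one-sided p < alpha
    mean_difference: float  # observed - ensemble mean
    n_sim: int


def _first50_mask(segments: pd.DataFrame, first_km: float = 50.0) -> np.ndarray:
    cum = segments["cum_length_km"].to_numpy(float)
    seg_len = np.diff(np.concatenate([[0.0], cum]))
    return (cum - seg_len) < first_km


def random_departures(
    track: Track,
    grid: WindGrid,
    season_window: tuple,
    n_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
    statistic: str = "first50",
    level: str = "750m",
    mode: str = "continuous",
    alpha: float = 0.05,
) -> NullDistribution:
    """Compare observed mean wind support with random departures.

    Each simulated departure displaces the whole track rigidly in time
    to a departure drawn from ``season_window`` (first to last departure
    of the season): uniformly in continuous time (``mode="continuous"``,
    default) or uniformly over whole nights keeping the observed
    time-of-day (``mode="nights"``).  The statistic (mean wind support
    over the first 50 km, or over the full track) is recomputed against
    the wind field for every draw.  Seeded runs are bit-reproducible.
    """
    t0 = np.datetime64(pd.Timestamp(season_window[0]), "s")
    t1 = np.datetime64(pd.Timestamp(season_window[1]), "s")
    if t1 <= t0:
        raise ValueError("degenerate season window (zero length)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    trimmed = track.ocean_trimmed()
    segments = annotate_track(trimmed, grid, level)
    mask = _first50_mask(segments) if statistic == "first50" else np.ones(len(segments), bool)
    if statistic not in {"first50", "full"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = float(segments["wind_support"].to_numpy()[mask].mean())

    dep = trimmed.times[0].astype("datetime64[s]")
    span_s = (t1 - t0).astype("int64")
    if mode == "continuous":
        new_dep_s = t0.astype("int64") + rng.uniform(0, span_s, size=n_sim)
        deltas = np.round(new_dep_s - dep.astype("int64")).astype("int64")
    elif mode == "nights":
        n_days = int(span_s // 86_400) + 1
        day_offsets = rng.integers(0, n_days, size=n_sim)
        base = (t0.astype("int64") - dep.astype("int64")) + day_offsets * 86_400
        deltas = base  # keeps the observed time-of-day relative to window start days
    else:
        raise ValueError(f"unknown mode {mode!r}")

    seg = segments.loc[mask]
    lons = seg["lon"].to_numpy(float)
    lats = seg["lat"].to_numpy(float)
    tsec = seg["t_start"].to_numpy("datetime64[s]").astype("int64")
    alpha_deg = seg["ground_direction"].to_numpy(float)
    sin_a = np.sin(np.radians(alpha_deg))
    cos_a = np.cos(np.radians(alpha_deg))

    # (n_sim, n_seg) query block, flattened through the vectorized sampler
    qt = (tsec[None, :] + deltas[:, None]).astype("datetime64[s]")
    n_seg = len(seg)
    u, v = sample_wind_arrays(
        grid,
        np.broadcast_to(lons, (n_sim, n_seg)).ravel(),
        np.broadcast_to(lats, (n_sim, n_seg)).ravel(),
        qt.ravel(),
        level,
    )
    ws = u.reshape(n_sim, n_seg) * sin_a + v.reshape(n_sim, n_seg) * cos_a
    simulated = ws.mean(axis=1)
    p = float(np.mean(simulated >= observed))
    return NullDistribution(
        track_id=track.id,
        statistic=statistic,
        level=level,
        observed=observed,
        simulated=simulated,
        p=p,
        significant=p < alpha,
        mean_difference=observed - float(simulated.mean()),
        n_sim=n_sim,
    )


@dataclass
class DeltaWind:
    """Westward-minus-eastward wind support for one departure night."""

    night: object  # calendar date of the departure night
    delta_w_minus_e: float
    ws_west: float
    ws_east: float
    west_bearing: float
    east_bearing: float
    level: str


def delta_wind_support(
    night,
    location: GeoPoint,
    grid: WindGrid,
    west_bearing: float = 270.0,
    east_bearing: float = 90.0,
    level: str = "750m",
    local_time: dt.time = dt.time(22, 30),
    utc_offset_h: float = -8.0,
) -> DeltaWind:
    """Wind support for flying west minus east at the mean departure hour.

    The wind is sampled at ``location`` at ``local_time`` (default 22:30
    local clock, UTC offset -8 h) on the given night, at one level, and
    projected onto the west and east reference bearings.  Swapping the
    bearings flips the sign exactly.
    """
    local = pd.Timestamp(dt.datetime.combine(pd.Timestamp(night).date(), local_time))
    t_utc = (local - pd.Timedelta(hours=utc_offset_h)).to_datetime64()
    w = sample_wind(grid, location, t_utc, level)
    ws_west, _, _ = wind_components(w.u, w.v, west_bearing)
    ws_east, _, _ = wind_components(w.u, w.v, east_bearing)
    return DeltaWind(
        night=pd.Timestamp(night).date(),
        delta_w_minus_e=ws_west - ws_east,
        ws_west=ws_west,
        ws_east=ws_east,
        west_bearing=west_bearing,
        east_bearing=east_bearing,
        level=level,
    )


@dataclass
class ShiftProfile:
    """Wind support toward the actual destination at shifted departures.

    ``hourly`` has offsets -12..+12 h against station ground wind;
    ``daily`` has offsets -5..+5 days per grid level.  Offsets without
    coverage carry NaN markers rather than failing the profile.
    """

    track_id: str
    destination_bearing: float
    hourly: pd.DataFrame  # columns offset_h, ws
    daily: pd.DataFrame  # columns offset_d, level, ws


def departure_shift_profile(
    track: Track,
    grid: WindGrid,
    station: pd.DataFrame,
    hour_range: int = 12,
    day_range: int = 5,
    station_tolerance: pd.Timedelta = pd.Timedelta(minutes=30),
) -> ShiftProfile:
    """Would the bird have had better winds a few hours or days away?

    Wind support is evaluated toward the great-circle bearing from the
    departure to the actual arrival location, at the actual departure
    time shifted hour-by-hour (station series) and day-by-day (gridded
    wind, every level).
    """
    trimmed = track.ocean_trimmed()
    dep_p = trimmed.point(0)
    arr_p = trimmed.point(len(trimmed) - 1)
    bearing = geo.initial_bearing_deg(dep_p, arr_p)
    if bearing is None:
        raise ValueError(f"track {track.id!r}: coincident departure and arrival")
    dep_t = pd.Timestamp(trimmed.times[0])

    idx = station.index
    hourly_rows = []
    for off in range(-hour_range, hour_range + 1):
        t = dep_t + pd.Timedelta(hours=off)
        ws = np.nan
        if len(idx):
            pos = idx.get_indexer([t], method="nearest")[0]
            if pos >= 0 and abs(idx[pos] - t) <= station_tolerance:
                row = station.iloc[pos]
                ws, _, _ = wind_components(row["u"], row["v"], bearing)
        hourly_rows.append({"offset_h": off, "ws": ws})

    daily_rows = []
    for off in range(-day_range, day_range + 1):
        t = (dep_t + pd.Timedelta(days=off)).to_datetime64()
        for level in grid.levels:
            try:
                w = sample_wind(grid, dep_p, t, level)
                ws, _, _ = wind_components(w.u, w.v, bearing)
            except ValueError:
                ws = np.nan
            daily_rows.append({"offset_d": off, "level": level, "ws": ws})

    return ShiftProfile(
        track_id=track.id,
        destination_bearing=bearing,
        hourly=pd.DataFrame(hourly_rows),
        daily=pd.DataFrame(daily_rows),
    )
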
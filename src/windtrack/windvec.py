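"""Wind support, crosswind and air speed along tracks.

For a ground (movement) vector with direction ``alpha`` (degrees
clockwise from north) and a wind vector ``(u, v)``:

* wind support  ``Ws = u*sin(alpha) + v*cos(alpha)`` — the signed length
  of the wind vector projected onto the ground vector; positive means
  tailwind, negative headwind;
* crosswind     ``Cw = |u*cos(alpha) - v*sin(alpha)|`` — the magnitude
  of the perpendicular component, side-agnostic;
* relative wind support ``Ws / |wind|`` — the cosine of the angle
  between wind and track, in [-1, +1]; defined as 0 in calm air
  (no flow, no support);
* air speed     ``ground_speed - Ws`` — the scalar approximation of the
  bird's own effort used throughout this analysis.

These satisfy ``Ws**2 + Cw**2 = u**2 + v**2`` identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .tracks import Track
from .windfield import WindGrid, sample_wind_arrays

__all__ = ["wind_components", "annotate_track", "max_ws_altitude", "AltitudeProfile"]


def wind_components(u, v, alpha):
    """(wind support, crosswind, relative wind support) for wind ``(u, v)``
    and ground direction ``alpha`` in degrees clockwise from north.

    Total function; accepts scalars or arrays.  Calm air (zero wind
    speed) yields relative support 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    rad = np.radians(np.asarray(alpha, dtype=float))
    ws = u * np.sin(rad) + v * np.cos(rad)
    cw = np.abs(u * np.cos(rad) - v * np.sin(rad))
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(speed > 0, ws / np.where(speed > 0, speed, 1.0), 0.0)
    if ws.ndim == 0:
        return float(ws), float(cw), float(rel)
    return ws, cw, rel


def annotate_track(
    track: Track,
    grid: WindGrid,
    level: str,
    sample_at: str = "start",
    time_mode: str = "nearest",
) -> pd.DataFrame:
    """Per-segment ground speed/direction and wind metrics for one track.

    One row per consecutive position pair.  Ground speed is geodesic
    segment distance over elapsed time; the wind is sampled nearest in
    space and time at the segment start (``sample_at="midpoint"`` uses
    the segment midpoint in space and time instead).

    Columns: track_id, t_start, t_end, lon, lat, ground_speed,
    ground_direction, u, v, wind_speed, wind_support, crosswind,
    relative_wind_support, air_speed, level, cum_length_km.
    """
    lengths = track.segment_lengths_m()
    dt = np.diff(track.times.astype("int64")).astype(float)
    alpha = geo.segment_bearings_deg(track.lons, track.lats)
    if sample_at == "start":
        qlon, qlat, qt = track.lons[:-1], track.lats[:-1], track.times[:-1]
    elif sample_at == "midpoint":
        qlon = 0.5 * (track.lons[:-1] + track.lons[1:])
        qlat = 0.5 * (track.lats[:-1] + track.lats[1:])
        qt = track.times[:-1] + (track.times[1:] - track.times[:-1]) // 2
    else:
        raise ValueError(f"unknown sample_at {sample_at!r}")
    try:
        u, v = sample_wind_arrays(grid, qlon, qlat, qt, level, time_mode=time_mode)
    except ValueError as exc:
        raise ValueError(f"track {track.id!r}: wind coverage gap ({exc})") from exc
    ground_speed = lengths / dt
    # stationary segments have no direction; treat as zero support/crosswind
    alpha_filled = np.where(np.isnan(alpha), 0.0, alpha)
    ws, cw, rel = wind_components(u, v, alpha_filled)
    ws = np.where(np.isnan(alpha), 0.0, ws)
    cw = np.where(np.isnan(alpha), np.hypot(u, v), cw)
    rel = np.where(np.isnan(alpha), 0.0, rel)
    cum_km = np.cumsum(lengths) / 1000.0
    return pd.DataFrame(
        {
            "track_id": track.id,
            "t_start": track.times[:-1],
            "t_end": track.times[1:],
            "lon": track.lons[:-1],
            "lat": track.lats[:-1],
            "ground_speed": ground_speed,
            "ground_direction": alpha,
            "u": u,
            "v": v,
            "wind_speed": np.hypot(u, v),
            "wind_support": ws,
            "crosswind": cw,
            "relative_wind_support": rel,
            "air_speed": ground_speed - ws,
            "level": level,
            "cum_length_km": cum_km,
        }
    )


@dataclass
class AltitudeProfile:
    """Hour-by-hour best-support altitude and the resulting track means.

    ``maxws_mean`` is the mean over 1-h windows of the winning level's
    window-mean wind support; ``fixed_level_means`` are the same
    window-weighted means for each fixed level, so the max-support mean
    dominates every fixed level by construction.
    """

    track_id: str
    window_starts: np.ndarray  # datetime64[s] of each 1-h window
    chosen_levels: list[str]  # winning level per window
    chosen_means: np.ndarray  # that level's window-mean wind support
    maxws_mean: float
    fixed_level_means: dict[str, float]


def max_ws_altitude(track: Track, grid: WindGrid, window_h: float = 1.0) -> AltitudeProfile:
    """The altitude profile a bird maximizing wind support could have flown.

    The track is cut into consecutive windows of ``window_h`` hours
    anchored at departure (final partial window included).  Per window,
    the level whose mean wind support over the window's segments is
    highest wins; ties go to the lower altitude.
    """
    span_s = float((track.times[-1] - track.times[0]) / np.timedelta64(1, "s"))
    if span_s < 3600 * window_h:
        raise ValueError(f"track {track.id!r} spans less than one {window_h}-h window")
    if (track.times[-1] - track.times[0]) < grid.time_step:
        raise ValueError(f"track {track.id!r} is shorter than one wind time step")
    per_level = {lv: annotate_track(track, grid, lv)["wind_support"].to_numpy() for lv in grid.levels}
    seg_start = track.times[:-1]
    offsets_s = (seg_start - track.times[0]).astype("int64")
    win = (offsets_s // int(3600 * window_h)).astype(int)
    starts, chosen, means = [], [], []
    fixed_window_means = {lv: [] for lv in grid.levels}
    for w in np.unique(win):
        sel = win == w
        level_means = np.array([per_level[lv][sel].mean() for lv in grid.levels])
        best = int(np.argmax(level_means))  # argmax -> first max -> lower altitude on tie
        starts.append(track.times[0] + np.timedelta64(int(w * 3600 * window_h), "s"))
        chosen.append(grid.levels[best])
        means.append(level_means[best])
        for lv, m in zip(grid.levels, level_means):
            fixed_window_means[lv].append(m)
    return AltitudeProfile(
        track_id=track.id,
        window_starts=np.array(starts, dtype="datetime64[s]"),
        chosen_levels=chosen,
        chosen_means=np.array(means),
        maxws_mean=float(np.mean(means)),
        fixed_level_means={lv: float(np.mean(v)) for lv, v in fixed_window_means.items()},
    )


def annotate_max_ws(track: Track, grid: WindGrid, window_h: float = 1.0) -> pd.DataFrame:
    """Segment annotation where each 1-h window uses its best-support level.

    This is the segment table backing the "max wind support" entry in
    the seven-way flight-altitude model comparison.
    """
    profile = max_ws_altitude(track, grid, window_h=window_h)
    frames = {lv: annotate_track(track, grid, lv) for lv in grid.levels}
    offsets_s = (track.times[:-1] - track.times[0]).astype("int64")
    win = (offsets_s // int(3600 * window_h)).astype(int)
    win_to_level = dict(zip(np.unique(win), profile.chosen_levels))
    rows = []
    for i, w in enumerate(win):
        rows.append(frames[win_to_level[w]].iloc[i])
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["level"] = "maxWs"
    return out
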
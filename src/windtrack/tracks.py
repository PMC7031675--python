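"""Track containers, selection filters, summary metrics and flight classes.

A :class:`Track` is a time-ordered sequence of geographic positions at a
nominal 15-min spacing, with a per-point ocean/land label.  Summaries are
computed on the over-ocean span of the track (from the first to the last
ocean-labelled position): positions after landfall reflect behaviour over
land and are excluded from flight metrics.

Straightness here is track length divided by the geodesic
departure-arrival distance, so 1 means a perfectly direct flight and
large values mean loop-like flights (note this is the *inverse* of the
straightness index used in parts of the movement literature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
import shapely

from . import geo
from .geo import GeoPoint

__all__ = [
    "Track",
    "TrackSummary",
    "FlightClass",
    "read_tracks",
    "read_coastline",
    "label_surface",
    "select_tracks",
    "summarize_track",
    "classify_flight",
]

#: Local clock offset (hours from UTC) used for departure-time statistics.
#: The study region runs on Alaska Daylight Time.
DEFAULT_UTC_OFFSET_H = -8.0


@dataclass
class Track:
    """One flight: id, season and time-ordered positions with surface labels."""

    id: str
    season: int
    times: np.ndarray  # datetime64[s], strictly increasing
    lons: np.ndarray
    lats: np.ndarray
    ocean: np.ndarray | None = None  # per-point True over ocean; None = unlabelled

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValueError(f"track {self.id!r} needs >= 2 points, got {n}")
        if not (len(self.lons) == len(self.lats) == n):
            raise ValueError(f"track {self.id!r}: coordinate/time length mismatch")
        dt = np.diff(self.times.astype("int64"))
        if (dt <= 0).any():
            raise ValueError(f"track {self.id!r}: timestamps not strictly increasing")
        if self.ocean is not None:
            self.ocean = np.asarray(self.ocean, dtype=bool)
            if len(self.ocean) != n:
                raise ValueError(f"track {self.id!r}: surface label length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    def point(self, i: int) -> GeoPoint:
        return GeoPoint(lon=self.lons[i], lat=self.lats[i])

    def shifted(self, delta: np.timedelta64) -> "Track":
        """The same spatial path rigidly displaced in time by ``delta``."""
        return replace(self, times=self.times + delta)

    def segment_lengths_m(self) -> np.ndarray:
        return geo.pairwise_distances_m(self.lons, self.lats)

    def length_km(self) -> float:
        return float(self.segment_lengths_m().sum() / 1000.0)

    def ocean_span(self) -> tuple[int, int]:
        """(first, last) indices of ocean-labelled positions (inclusive)."""
        if self.ocean is None:
            return 0, len(self) - 1
        idx = np.nonzero(self.ocean)[0]
        if len(idx) == 0:
            raise ValueError(f"track {self.id!r} has no over-ocean positions")
        return int(idx[0]), int(idx[-1])

    def ocean_trimmed(self) -> "Track":
        """Sub-track from the first to the last over-ocean position."""
        i, j = self.ocean_span()
        if j - i < 1:
            raise ValueError(f"track {self.id!r} has fewer than 2 over-ocean positions")
        return replace(
            self,
            times=self.times[i : j + 1],
            lons=self.lons[i : j + 1],
            lats=self.lats[i : j + 1],
            ocean=None if self.ocean is None else self.ocean[i : j + 1],
        )


class FlightClass(str, Enum):
    DIRECTED_EAST = "directed-east"
    DIRECTED_WEST = "directed-west"
    LOOP = "loop"


@dataclass(frozen=True)
class TrackSummary:
    """Per-track flight metrics over the ocean span."""

    track_id: str
    season: int
    departure_time: pd.Timestamp  # first ocean position (UTC)
    arrival_time: pd.Timestamp  # last ocean position (UTC)
    flight_time_h: float
    track_length_km: float
    shortest_distance_km: float  # departure -> arrival geodesic
    detour_km: float
    percent_detour: float
    straightness: float
    departure_day: object  # calendar date after subtracting 12 h local
    initial_direction: float  # bearing of the first-50-km displacement
    final_direction: float | None  # departure -> arrival bearing; None if coincident
    n_points: int


def read_coastline(path) -> shapely.Geometry:
    """Read a land polygon (GeoJSON, lon/lat) used for ocean/land labelling."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely.geometry.shape(f["geometry"]) for f in gj["features"]]
        return shapely.unary_union(geoms)
    if gj.get("type") == "Feature":
        return shapely.geometry.shape(gj["geometry"])
    return shapely.geometry.shape(gj)


def label_surface(track: Track, land: shapely.Geometry) -> Track:
    """Attach ocean/land labels: a point is ocean iff outside the land polygon."""
    on_land = shapely.contains_xy(land, track.lons, track.lats)
    return replace(track, ocean=~on_land)


def read_tracks(path, land: shapely.Geometry | None = None) -> list[Track]:
    """Read tracks from CSV with columns id, timestamp, lon, lat.

    Rows are grouped by id and sorted by time; duplicate or non-monotone
    timestamps within an id are an error.  An optional ``surface`` column
    ("ocean"/"land") or a ``land`` polygon provides the ocean labels.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"id", "timestamp", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    out: list[Track] = []
    for tid, g in df.groupby("id", sort=True):
        g = g.sort_values("timestamp")
        times = g["timestamp"].to_numpy(dtype="datetime64[s]")
        if (np.diff(times.astype("int64")) <= 0).any():
            raise ValueError(f"track {tid!r}: duplicate or non-monotone timestamps")
        ocean = None
        if "surface" in g.columns:
            ocean = (g["surface"].astype(str).str.lower() == "ocean").to_numpy()
        season = int(pd.Timestamp(times[0]).year)
        t = Track(
            id=str(tid), season=season, times=times,
            lons=g["lon"].to_numpy(float), lats=g["lat"].to_numpy(float), ocean=ocean,
        )
        if ocean is None and land is not None:
            t = label_surface(t, land)
        out.append(t)
    return out


def _departure_index(track: Track) -> int | None:
    if track.ocean is None:
        return 0
    idx = np.nonzero(track.ocean)[0]
    return int(idx[0]) if len(idx) else None


def select_tracks(
    tracks: list[Track],
    origin: GeoPoint,
    cutoff_date,
    min_length_km: float = 500.0,
    radius_km: float = 250.0,
) -> list[Track]:
    """Apply the four track-selection filters.

    A track is kept iff (i) its departure date (UTC date of the first
    over-ocean position) is before ``cutoff_date``; (ii) the departure
    location is within ``radius_km`` of ``origin``; (iii) the departure
    leg is over ocean (the first ocean run has at least two consecutive
    positions, excluding over-land departures); (iv) the over-ocean track
    length exceeds ``min_length_km``.
    """
    cutoff = pd.Timestamp(cutoff_date).date()
    kept = []
    for t in tracks:
        dep = _departure_index(t)
        if dep is None:
            continue
        if pd.Timestamp(t.times[dep]).date() >= cutoff:
            continue
        if geo.distance_m(t.point(dep), origin) > radius_km * 1000.0:
            continue
        if t.ocean is not None:
            if dep + 1 >= len(t) or not t.ocean[dep + 1]:
                continue  # over-land departure: no ocean segment leaves the start
        try:
            trimmed = t.ocean_trimmed()
        except ValueError:
            continue
        if trimmed.length_km() <= min_length_km:
            continue
        kept.append(t)
    return kept


def _initial_direction(track: Track, first_km: float) -> float:
    """Bearing of the displacement accumulated over the first ``first_km``.

    Segments are accumulated until the cumulative track length reaches
    ``first_km``; the crossing segment is included in full.  Tracks
    shorter than ``first_km`` use their full extent.
    """
    cum = np.cumsum(track.segment_lengths_m()) / 1000.0
    idx = int(np.searchsorted(cum, first_km))
    end = min(idx + 1, len(track) - 1)
    b = geo.initial_bearing_deg(track.point(0), track.point(end))
    return float("nan") if b is None else b


def summarize_track(
    track: Track,
    utc_offset_h: float = DEFAULT_UTC_OFFSET_H,
    initial_km: float = 50.0,
) -> TrackSummary:
    """Compute the flight-description variables for one track.

    Works on the over-ocean span.  ``departure_day`` groups nocturnal
    departures into one calendar night by subtracting 12 h from the
    local clock time before taking the date.
    """
    t = track.ocean_trimmed()
    lengths = t.segment_lengths_m()
    track_length_km = float(lengths.sum() / 1000.0)
    dep, arr = t.point(0), t.point(len(t) - 1)
    shortest_km = geo.distance_m(dep, arr) / 1000.0
    detour = track_length_km - shortest_km
    departure = pd.Timestamp(t.times[0])
    arrival = pd.Timestamp(t.times[-1])
    flight_h = (arrival - departure).total_seconds() / 3600.0
    if flight_h <= 0:
        raise ValueError(f"track {track.id!r}: non-positive flight time")
    local_dep = departure + pd.Timedelta(hours=utc_offset_h)
    departure_day = (local_dep - pd.Timedelta(hours=12)).date()
    straightness = track_length_km / shortest_km if shortest_km > 0 else float("inf")
    percent_detour = 100.0 * detour / track_length_km if track_length_km > 0 else 0.0
    return TrackSummary(
        track_id=track.id,
        season=track.season,
        departure_time=departure,
        arrival_time=arrival,
        flight_time_h=flight_h,
        track_length_km=track_length_km,
        shortest_distance_km=shortest_km,
        detour_km=max(detour, 0.0),
        percent_detour=max(percent_detour, 0.0),
        straightness=straightness,
        departure_day=departure_day,
        initial_direction=_initial_direction(t, initial_km),
        final_direction=geo.initial_bearing_deg(dep, arr),
        n_points=len(t),
    )


def classify_flight(s: TrackSummary, loop_threshold: float = 3.0) -> FlightClass:
    """Loop if straightness >= ``loop_threshold``; otherwise directed east or
    west by the sign of the eastward component of the final direction.

    The threshold default sits in the gap between observed directed
    flights (straightness up to ~2.3) and loop flights (from ~5.1).
    """
    if s.straightness >= loop_threshold:
        return FlightClass.LOOP
    if s.final_direction is not None and 0.0 < s.final_direction < 180.0:
        return FlightClass.DIRECTED_EAST
    return FlightClass.DIRECTED_WEST


def summaries_frame(summaries: list[TrackSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per track) for model fitting and export."""
    df = pd.DataFrame([vars(s) for s in summaries])
    if len(df):
        df["flight_class"] = [classify_flight(s).value for s in summaries]
    return df
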
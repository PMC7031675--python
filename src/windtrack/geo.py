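"""Spherical geodesy primitives.

All distances and bearings in this package are computed on a sphere of
radius :data:`EARTH_RADIUS_M` (6,371,000 m).  At the spatial scales of
over-sea flights (hundreds to a few thousand km) the difference to an
ellipsoid is below 0.5% and well inside every tolerance used downstream,
while keeping closed-form checks exact.

Conventions
-----------
* Longitudes are decimal degrees east, normalized to ``[-180, 180)``.
* Latitudes are decimal degrees north in ``[-90, 90]``.
* Bearings are degrees clockwise from geographic north in ``[0, 360)``.
* The bearing between coincident points is undefined and returned as
  ``None`` (a sentinel, never a number).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "GeoPoint",
    "distance_and_bearing",
    "destination_point",
    "distance_m",
    "initial_bearing_deg",
    "pairwise_distances_m",
    "laea_project",
]


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into the half-open interval [-180, 180)."""
    return (lon + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position (decimal degrees, WGS84 axes, spherical model)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", normalize_lon(float(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


def _haversine_rad(lon1, lat1, lon2, lat2):
    """Central angle (radians) between points given in radians. Array-safe."""
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_m(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points in metres."""
    return float(
        EARTH_RADIUS_M
        * _haversine_rad(
            math.radians(a.lon), math.radians(a.lat), math.radians(b.lon), math.radians(b.lat)
        )
    )


def initial_bearing_deg(a: GeoPoint, b: GeoPoint) -> float | None:
    """Initial great-circle bearing from ``a`` to ``b``; ``None`` if coincident."""
    if a.lon == b.lon and a.lat == b.lat:
        return None
    lam1, phi1 = math.radians(a.lon), math.radians(a.lat)
    lam2, phi2 = math.radians(b.lon), math.radians(b.lat)
    dlon = lam2 - lam1
    x = math.sin(dlon) * math.cos(phi2)
    y = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlon)
    if x == 0.0 and y == 0.0:  # antipodal: bearing genuinely undefined
        return None
    return math.degrees(math.atan2(x, y)) % 360.0


def distance_and_bearing(a: GeoPoint, b: GeoPoint) -> tuple[float, float | None]:
    """Great-circle distance (m) and initial bearing (deg) from ``a`` to ``b``.

    For coincident points the distance is 0 and the bearing is the
    ``None`` sentinel.
    """
    d = distance_m(a, b)
    if d == 0.0:
        return 0.0, None
    return d, initial_bearing_deg(a, b)


def destination_point(a: GeoPoint, bearing_deg: float, distance: float) -> GeoPoint:
    """The point reached from ``a`` travelling ``distance`` metres on the
    great circle with the given initial bearing.

    Raises
    ------
    ValueError
        If ``distance`` is negative, or so large that the antipode of
        ``a`` would be crossed (outside the modelled regime).
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    delta = distance / EARTH_RADIUS_M
    if delta >= math.pi:
        raise ValueError(
            f"distance {distance:.0f} m crosses the antipode (max {math.pi * EARTH_RADIUS_M:.0f} m)"
        )
    if distance == 0.0:
        return a
    theta = math.radians(bearing_deg)
    phi1 = math.radians(a.lat)
    lam1 = math.radians(a.lon)
    sin_phi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    phi2 = math.asin(max(-1.0, min(1.0, sin_phi2)))
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sin_phi2,
    )
    return GeoPoint(lon=math.degrees(lam2), lat=math.degrees(phi2))


def pairwise_distances_m(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Distances (m) between consecutive positions of a track.

    Vectorized companion of :func:`distance_m`; returns ``len(lons) - 1``
    segment lengths.
    """
    lons = np.radians(np.asarray(lons, dtype=float))
    lats = np.radians(np.asarray(lats, dtype=float))
    return EARTH_RADIUS_M * _haversine_rad(lons[:-1], lats[:-1], lons[1:], lats[1:])


def segment_bearings_deg(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Initial bearings (deg) of consecutive track segments, NaN where stationary."""
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    dlon = lam[1:] - lam[:-1]
    x = np.sin(dlon) * np.cos(phi[1:])
    y = np.cos(phi[:-1]) * np.sin(phi[1:]) - np.sin(phi[:-1]) * np.cos(phi[1:]) * np.cos(dlon)
    out = np.degrees(np.arctan2(x, y)) % 360.0
    out[(x == 0) & (y == 0)] = np.nan
    return out


def laea_project(
    lons: np.ndarray, lats: np.ndarray, lon0: float = -156.65, lat0: float = 90.0
) -> tuple[np.ndarray, np.ndarray]:
    """Polar Lambert azimuthal equal-area projection, for map output only.

    Centred by default on the pole with longitude origin 156.65° W (the
    study site's meridian).  Analyses never run in projected coordinates;
    this exists so plotted maps preserve area.
    """
    lam = np.radians(np.asarray(lons, dtype=float) - lon0)
    phi = np.radians(np.asarray(lats, dtype=float))
    phi0 = math.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    k = EARTH_RADIUS_M * np.sqrt(2.0 / denom)
    x = k * np.cos(phi) * np.sin(lam)
    y = k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y
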
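"""Counterfactual shortest-route flights.

Given a fitted speed model and a wind field, simulate the flight a bird
would have made had it headed straight for its destination: at every
15-min step the bearing to the (fixed) arrival point is re-evaluated
(a "constant heading towards" a fixed point is not a fixed compass
bearing on a sphere), the local wind support and crosswind for that
bearing are computed, and the ground speed predicted by the model's
fixed effects carries the bird forward.  A negative predicted speed
conservatively stalls the bird in place for that step rather than
moving it backwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .geo import GeoPoint
from .models import SpeedModelFit
from .tracks import Track
from .windfield import WindGrid, sample_wind
from .windvec import wind_components

__all__ = ["SimRoute", "simulate_shortest_route", "compare_routes", "predict_ground_speed"]

STEP_S = 900.0  # 15-min simulation step


def predict_ground_speed(model: SpeedModelFit, ws: float, cw: float) -> float:
    """Population-level (fixed effects only) ground-speed prediction."""
    c = model.coefficients
    speed = c["intercept"] + c["wind_support"] * ws + c["crosswind"] * cw
    if "interaction" in c:
        speed += c["interaction"] * ws * cw
    return float(speed)


@dataclass
class SimRoute:
    """A simulated direct flight at 15-min resolution."""

    departure: GeoPoint
    arrival: GeoPoint
    times: np.ndarray  # datetime64[s] per simulated position
    lons: np.ndarray
    lats: np.ndarray
    wind_support: np.ndarray  # per step taken (toward-destination bearing)
    flight_time_h: float
    mean_ws: float
    stalled_steps: int
    status: str  # "arrived" or "max-steps-exceeded"


def simulate_shortest_route(
    dep: GeoPoint,
    arr: GeoPoint,
    t0,
    grid: WindGrid,
    model: SpeedModelFit,
    level: str = "750m",
    max_steps: int | None = None,
) -> SimRoute:
    """Simulate the direct departure->arrival flight under the wind field.

    The bird arrives when the remaining distance is within one
    step-reach at the current predicted speed; the final step is clamped
    onto the destination so the route never overshoots.  ``max_steps``
    defaults to four times the closed-form no-wind step count (distance
    over the model intercept speed); exceeding it returns status
    ``"max-steps-exceeded"`` with the partial route.
    """
    t = np.datetime64(pd.Timestamp(t0), "s")
    total_m = geo.distance_m(dep, arr)
    if max_steps is None:
        v0 = max(model.coefficients["intercept"], 1.0)
        max_steps = max(4 * math.ceil(total_m / (v0 * STEP_S)), 8)

    pos = dep
    times = [t]
    lons = [dep.lon]
    lats = [dep.lat]
    ws_list: list[float] = []
    stalled = 0
    status = "max-steps-exceeded"
    if total_m == 0.0:
        status = "arrived"
        max_steps = 0
    for _ in range(max_steps):
        remaining, bearing = geo.distance_and_bearing(pos, arr)
        if bearing is None:
            status = "arrived"
            break
        try:
            w = sample_wind(grid, pos, t, level)
        except ValueError as exc:
            raise RouteCoverageError(
                f"wind coverage exhausted at {pos} / {t}",
                partial=_as_route(dep, arr, times, lons, lats, ws_list, stalled, "coverage-error"),
            ) from exc
        ws, cw, _ = wind_components(w.u, w.v, bearing)
        speed = predict_ground_speed(model, ws, cw)
        t = t + np.timedelta64(int(STEP_S), "s")
        if speed <= 0.0:
            stalled += 1  # the conservative stall rule: never move backwards
            times.append(t)
            lons.append(pos.lon)
            lats.append(pos.lat)
            ws_list.append(ws)
            continue
        step_m = speed * STEP_S
        ws_list.append(ws)
        if remaining <= step_m:
            pos = arr  # clamp the final step onto the destination
            times.append(t)
            lons.append(pos.lon)
            lats.append(pos.lat)
            status = "arrived"
            break
        pos = geo.destination_point(pos, bearing, step_m)
        times.append(t)
        lons.append(pos.lon)
        lats.append(pos.lat)
    return _as_route(dep, arr, times, lons, lats, ws_list, stalled, status)


def _as_route(dep, arr, times, lons, lats, ws_list, stalled, status) -> SimRoute:
    times = np.array(times, dtype="datetime64[s]")
    flight_h = float((times[-1] - times[0]).astype("int64") / 3600.0)
    ws = np.array(ws_list, dtype=float)
    return SimRoute(
        departure=dep,
        arrival=arr,
        times=times,
        lons=np.array(lons),
        lats=np.array(lats),
        wind_support=ws,
        flight_time_h=flight_h,
        mean_ws=float(ws.mean()) if len(ws) else float("nan"),
        stalled_steps=stalled,
        status=status,
    )


class RouteCoverageError(ValueError):
    """Wind coverage ran out mid-route; carries the partial route."""

    def __init__(self, msg: str, partial: SimRoute):
        super().__init__(msg)
        self.partial = partial


@dataclass
class RouteComparison:
    """Actual vs. shortest-route flight for one track.

    ``delta_mean_ws`` is mean wind support on the actual track minus on
    the simulated direct route (positive: the real route caught more
    tailwind).  ``delta_time_h`` is actual flight time minus simulated
    direct flight time (positive: the direct route would have saved
    time).  ``delta_time_h`` is NaN when the simulation never arrived.
    """

    track_id: str
    delta_mean_ws: float
    delta_time_h: float
    actual_mean_ws: float
    sim_mean_ws: float
    actual_time_h: float
    sim_time_h: float
    sim_status: str


def compare_routes(
    track: Track, segments: pd.DataFrame, sim: SimRoute, endpoint_tol_km: float = 1.0
) -> RouteComparison:
    """Signed actual-minus-shortest differences for one track."""
    trimmed = track.ocean_trimmed()
    dep, arr = trimmed.point(0), trimmed.point(len(trimmed) - 1)
    if (
        geo.distance_m(dep, sim.departure) > endpoint_tol_km * 1000.0
        or geo.distance_m(arr, sim.arrival) > endpoint_tol_km * 1000.0
    ):
        raise ValueError(f"track {track.id!r}: simulated route endpoints do not match")
    actual_ws = float(segments["wind_support"].mean())
    actual_h = float(
        (trimmed.times[-1] - trimmed.times[0]).astype("int64") / 3600.0
    )
    sim_h = sim.flight_time_h if sim.status == "arrived" else float("nan")
    return RouteComparison(
        track_id=track.id,
        delta_mean_ws=actual_ws - sim.mean_ws,
        delta_time_h=actual_h - sim_h,
        actual_mean_ws=actual_ws,
        sim_mean_ws=sim.mean_ws,
        actual_time_h=actual_h,
        sim_time_h=sim_h,
        sim_status=sim.status,
    )


def aggregate_comparisons(
    comparisons: list[RouteComparison], classes: dict[str, str]
) -> pd.DataFrame:
    """Per-flight-class means of the actual-vs-shortest differences."""
    df = pd.DataFrame([vars(c) for c in comparisons])
    df["flight_class"] = df["track_id"].map(classes)
    return (
        df.groupby("flight_class")[["delta_mean_ws", "delta_time_h"]]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
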
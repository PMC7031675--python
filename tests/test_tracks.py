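"""Track reading, selection filters, summary metrics and classification."""

import numpy as np
import pandas as pd
import pytest

from windtrack import geo
from windtrack.geo import GeoPoint
from windtrack.tracks import (
    FlightClass,
    classify_flight,
    read_tracks,
    select_tracks,
    summarize_track,
)

from conftest import make_track


def test_read_tracks_groups_and_sorts(tmp_path):
    rows = []
    for i in (2, 0, 1):
        rows.append({"id": "a", "timestamp": f"2012-06-01T00:{15 * i:02d}:00", "lon": i * 0.1, "lat": 70.0})
    rows.append({"id": "b", "timestamp": "2012-06-01T00:00:00", "lon": 0, "lat": 70})
    rows.append({"id": "b", "timestamp": "2012-06-01T00:15:00", "lon": 0.1, "lat": 70})
    path = tmp_path / "tracks.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    out = read_tracks(path)
    assert [t.id for t in out] == ["a", "b"]
    assert len(out[0]) == 3
    assert np.all(np.diff(out[0].times.astype("int64")) > 0)
    assert out[0].lons[0] == 0.0  # shuffled rows sorted by time


def test_read_tracks_duplicate_timestamp_errors(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame(
        {
            "id": ["x", "x"],
            "timestamp": ["2012-06-01T00:00:00"] * 2,
            "lon": [0.0, 0.1],
            "lat": [70.0, 70.0],
        }
    ).to_csv(path, index=False)
    with pytest.raises(ValueError, match="'x'"):
        read_tracks(path)


def _straight_track(tid, start, bearing, n_points, t0, ocean=True, speed=16.0):
    pts = [start]
    for _ in range(n_points - 1):
        pts.append(geo.destination_point(pts[-1], bearing, speed * 900.0))
    return make_track(
        tid=tid, t0=t0, lons=[p.lon for p in pts], lats=[p.lat for p in pts], ocean=ocean
    )


def test_select_tracks_one_criterion_violated_each():
    """Five tracks each violate exactly one filter; one passes all four."""
    origin = GeoPoint(-156.73, 71.3)
    n = 60  # ~860 km at 16 m/s
    ok = _straight_track("pass", origin, 90.0, n, "2012-06-05T06:00:00")
    late = _straight_track("late", origin, 90.0, n, "2012-07-09T06:00:00")
    far = _straight_track("far", geo.destination_point(origin, 0.0, 400_000.0), 90.0, n, "2012-06-05T06:00:00")
    land = _straight_track("land", origin, 90.0, n, "2012-06-05T06:00:00")
    land.ocean = np.zeros(n, dtype=bool)
    land.ocean[25] = True  # a lone ocean fix: no over-ocean departure segment
    short = _straight_track("short", origin, 90.0, 10, "2012-06-05T06:00:00")
    kept = select_tracks([ok, late, far, land, short], origin, "2012-07-08")
    assert [t.id for t in kept] == ["pass"]
    assert select_tracks([], origin, "2012-07-08") == []


def test_two_point_geodesic_track_is_perfectly_straight():
    t = make_track(lons=[-156.0, -150.0], lats=[71.3, 71.5])
    s = summarize_track(t)
    assert s.straightness == pytest.approx(1.0)
    assert s.detour_km == pytest.approx(0.0)
    assert s.percent_detour == pytest.approx(0.0)


def test_l_shaped_track_detour_matches_spherical_oracle():
    """200 km east then 200 km north at the equator."""
    p0 = GeoPoint(0.0, 0.0)
    p1 = geo.destination_point(p0, 90.0, 200_000.0)
    p2 = geo.destination_point(p1, 0.0, 200_000.0)
    t = make_track(lons=[p0.lon, p1.lon, p2.lon], lats=[p0.lat, p1.lat, p2.lat], step_min=180)
    s = summarize_track(t)
    assert s.track_length_km == pytest.approx(400.0, rel=1e-6)
    diag = geo.distance_m(p0, p2) / 1000.0
    assert diag == pytest.approx(282.8, abs=0.5)
    assert s.straightness == pytest.approx(400.0 / diag, rel=1e-9)
    assert s.percent_detour == pytest.approx(100.0 * (400.0 - diag) / 400.0, rel=1e-9)
    assert s.percent_detour == pytest.approx(29.3, abs=0.2)


def test_departure_day_twelve_hour_rule():
    # 03:00 local on 7 June = 11:00 UTC at offset -8; minus 12 h -> 6 June
    t = make_track(t0="2012-06-07T11:00:00", lons=[-156.0, -155.0], lats=[71.3, 71.4])
    s = summarize_track(t)
    assert str(s.departure_day) == "2012-06-06"
    # and a 23:00 local departure also belongs to the night of 6 June... of 7th
    t2 = make_track(t0="2012-06-08T07:00:00", lons=[-156.0, -155.0], lats=[71.3, 71.4])
    assert str(summarize_track(t2).departure_day) == "2012-06-07"


def test_post_landfall_positions_excluded():
    """Trailing over-land positions do not count toward flight metrics."""
    lons = [-156.0, -155.0, -154.0, -153.0]
    lats = [71.5, 71.5, 71.5, 71.5]
    t = make_track(lons=lons, lats=lats, ocean=[True, True, True, False])
    s = summarize_track(t)
    t_ref = make_track(lons=lons[:3], lats=lats[:3])
    assert s.track_length_km == pytest.approx(summarize_track(t_ref).track_length_km)
    assert s.arrival_time == pd.Timestamp("2012-06-01T06:30:00")


def test_summarize_all_land_track_errors():
    t = make_track(lons=[-156.0, -155.0], lats=[70.0, 70.1], ocean=[False, False])
    with pytest.raises(ValueError, match="ocean"):
        summarize_track(t)


@pytest.mark.parametrize(
    "straightness,final_dir,expected",
    [
        (7.8, 40.0, FlightClass.LOOP),
        (1.1, 90.0, FlightClass.DIRECTED_EAST),
        (2.99, 270.0, FlightClass.DIRECTED_WEST),
        (3.0, 90.0, FlightClass.LOOP),
    ],
)
def test_classify_flight(straightness, final_dir, expected):
    from windtrack.tracks import TrackSummary

    s = TrackSummary(
        track_id="t", season=2012, departure_time=pd.Timestamp("2012-06-01"),
        arrival_time=pd.Timestamp("2012-06-02"), flight_time_h=24.0,
        track_length_km=1000.0, shortest_distance_km=1000.0 / straightness,
        detour_km=0.0, percent_detour=0.0, straightness=straightness,
        departure_day=pd.Timestamp("2012-05-31").date(), initial_direction=final_dir,
        final_direction=final_dir, n_points=10,
    )
    assert classify_flight(s) == expected


def test_track_length_equals_sum_of_pairwise_distances():
    rng = np.random.default_rng(2)
    lons = np.cumsum(rng.uniform(0.0, 0.1, 50)) - 156.0
    lats = 71.3 + np.cumsum(rng.normal(0, 0.02, 50))
    t = make_track(lons=lons, lats=lats)
    expect = sum(
        geo.distance_m(GeoPoint(lons[i], lats[i]), GeoPoint(lons[i + 1], lats[i + 1]))
        for i in range(49)
    )
    assert t.length_km() == pytest.approx(expect / 1000.0, rel=1e-12)


def test_straightness_at_least_one_on_random_tracks():
    rng = np.random.default_rng(9)
    for _ in range(1000):
        n = rng.integers(3, 12)
        lons = -156.0 + np.cumsum(rng.normal(0, 0.2, n))
        lats = 71.0 + np.cumsum(rng.normal(0, 0.1, n))
        s = summarize_track(make_track(lons=lons, lats=lats))
        assert s.straightness >= 1.0 - 1e-9
        assert s.detour_km >= -1e-9


def test_removing_interior_points_never_increases_length():
    rng = np.random.default_rng(4)
    lons = -156.0 + np.cumsum(rng.normal(0, 0.2, 30))
    lats = 71.0 + np.cumsum(rng.normal(0, 0.1, 30))
    full = make_track(lons=lons, lats=lats)
    keep = np.sort(np.r_[0, rng.choice(np.arange(1, 29), 10, replace=False), 29])
    sub = make_track(lons=lons[keep], lats=lats[keep])
    assert sub.length_km() <= full.length_km() + 1e-9
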
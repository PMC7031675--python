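import numpy as np
import pandas as pd
import pytest

from windtrack.tracks import Track
from windtrack.windfield import WindGrid


def make_grid(
    u=5.0,
    v=0.0,
    levels=("10m", "750m"),
    t0="2012-06-01",
    n_times=8,
    step_h=6,
    lats=(68.0, 80.0, 0.75),
    lons=(-180.0, -100.0, 0.75),
):
    """A small wind grid, constant unless u/v are given per (time, level)."""
    times = np.datetime64(t0, "s") + np.arange(n_times) * np.timedelta64(step_h * 3600, "s")
    lat_ax = np.arange(*lats[:2], lats[2])
    lon_ax = np.arange(*lons[:2], lons[2])
    heights = [float(lv.rstrip("m")) for lv in levels]
    shape = (n_times, len(levels), len(lat_ax), len(lon_ax))

    def expand(arr):
        arr = np.asarray(arr, float)
        if arr.ndim == 1 and len(arr) == len(levels) and len(levels) != n_times:
            arr = arr.reshape(1, len(levels), 1, 1)  # per-level values
        elif arr.ndim == 1 and len(arr) == n_times:
            arr = arr.reshape(n_times, 1, 1, 1)  # per-time values
        elif arr.ndim == 2:
            arr = arr.reshape(arr.shape + (1, 1))  # (time, level) values
        return np.broadcast_to(arr, shape).copy()

    uu, vv = expand(u), expand(v)
    return WindGrid(
        times=times, levels=list(levels), heights_m=np.array(heights),
        lats=lat_ax, lons=lon_ax, u=uu, v=vv,
    )


def make_track(tid="trk", t0="2012-06-01T06:00:00", lons=None, lats=None, step_min=15, ocean=True):
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    times = np.datetime64(t0, "s") + np.arange(len(lons)) * np.timedelta64(step_min * 60, "s")
    oc = np.full(len(lons), bool(ocean)) if np.ndim(ocean) == 0 else np.asarray(ocean, bool)
    return Track(id=tid, season=int(pd.Timestamp(t0).year), times=times, lons=lons, lats=lats, ocean=oc)


@pytest.fixture
def constant_grid():
    return make_grid(u=5.0, v=0.0)
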
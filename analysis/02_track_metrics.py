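"""Track selection and flight-description metrics.

Applies the four selection filters (departure date, distance from the
origin, over-ocean departure, minimum length), computes per-track
metrics (length, detour, straightness, directions, departure night) and
classifies flights as directed east/west or loops.  Writes
results/track_summaries.csv.
"""

import pandas as pd

from common import RESULTS, WORLD, ensure_world

from windtrack.geo import GeoPoint
from windtrack.tracks import (
    read_coastline,
    read_tracks,
    select_tracks,
    summaries_frame,
    summarize_track,
)


def main() -> None:
    paths = ensure_world()
    land = read_coastline(paths["coast"])
    tracks = read_tracks(paths["tracks"], land=land)
    origin = GeoPoint(WORLD.origin_lon, WORLD.origin_lat)
    kept = select_tracks(tracks, origin, cutoff_date="2012-07-08", min_length_km=100.0)
    print(f"{len(tracks)} tracks read, {len(kept)} pass the selection filters")

    summaries = [summarize_track(t) for t in kept]
    df = summaries_frame(summaries)
    out = RESULTS / "track_summaries.csv"
    df.to_csv(out, index=False)

    med = df["percent_detour"].median()
    print(f"median percentage detour: {med:.1f}%")
    for cls, g in df.groupby("flight_class"):
        print(
            f"  {cls}: n={len(g)}, median straightness {g['straightness'].median():.2f}, "
            f"median length {g['track_length_km'].median():.0f} km, "
            f"median flight time {g['flight_time_h'].median():.1f} h"
        )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
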
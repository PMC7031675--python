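"""Shortest-route counterfactuals: would the direct flight have been
cheaper or faster?

For every track, simulates a direct departure-to-arrival flight through
the same wind field (ground speed predicted from the fitted speed
model, 15-min steps, stalling on negative predictions), then compares
mean wind support and flight time between the actual and the direct
route, aggregated by flight class — loops are expected to gain wind
support at a large cost in time.  Writes results/route_comparison.csv.
"""

import pandas as pd

from common import RESULTS, ensure_world

from windtrack.models import fit_speed_model
from windtrack.routesim import (
    RouteCoverageError,
    aggregate_comparisons,
    compare_routes,
    simulate_shortest_route,
)
from windtrack.tracks import classify_flight, read_coastline, read_tracks, summarize_track
from windtrack.windfield import load_wind_grid
from windtrack.windvec import annotate_track


def main() -> None:
    paths = ensure_world()
    grid = load_wind_grid(paths["wind"])
    land = read_coastline(paths["coast"])
    tracks = [t.ocean_trimmed() for t in read_tracks(paths["tracks"], land=land)]
    tracks = [t for t in tracks if (t.times[-1] - t.times[0]) >= grid.time_step]
    level = "750m"

    seg_all = {t.id: annotate_track(t, grid, level) for t in tracks}
    model = fit_speed_model(pd.concat(seg_all.values(), ignore_index=True), level)
    classes = {t.id: classify_flight(summarize_track(t)).value for t in tracks}

    comparisons = []
    for t in tracks:
        dep = t.point(0)
        arr = t.point(len(t) - 1)
        try:
            sim = simulate_shortest_route(dep, arr, t.times[0], grid, model, level)
        except RouteCoverageError as exc:
            print(f"  {t.id}: skipped ({exc})")
            continue
        comparisons.append(compare_routes(t, seg_all[t.id], sim))

    df = pd.DataFrame([vars(c) for c in comparisons])
    df["flight_class"] = df["track_id"].map(classes)
    df.to_csv(RESULTS / "route_comparison.csv", index=False)
    arrived = df[df["sim_status"] == "arrived"]
    print(f"simulated {len(df)} direct routes ({len(arrived)} arrived)")
    agg = aggregate_comparisons(comparisons, classes)
    print("actual - shortest, by flight class "
          "(positive dWs: the real route caught more tailwind; "
          "positive dt: the direct route would have been faster):")
    print(agg.to_string(index=False))


if __name__ == "__main__":
    main()
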
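"""Build the synthetic study season.

Generates the shared world (tracks CSV, wind NetCDF, station CSV,
coastline GeoJSON, truth manifest) under results/world/ and prints what
was planted, so later scripts' recoveries can be judged against it.
"""

import json

from common import WORLD, WORLD_DIR, ensure_world

from windtrack.synth import write_world


def main() -> None:
    paths = write_world(WORLD, WORLD_DIR)
    with open(paths["manifest"]) as fh:
        manifest = json.load(fh)
    classes = [rec["class"] for rec in manifest["per_track"].values()]
    print(f"world written to {WORLD_DIR}")
    print(f"  tracks: {len(classes)} "
          f"(east {classes.count('directed-east')}, west {classes.count('directed-west')}, "
          f"loop {classes.count('loop')})")
    print(f"  active wind level (planted): {manifest['active_level']}")
    print(f"  planted speed law: ground = {manifest['speed_intercept']:.1f} "
          f"+ {manifest['speed_ws_coef']:.1f} * Ws (calm crosswind)")


if __name__ == "__main__":
    main()
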
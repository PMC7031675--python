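"""Shared configuration for the analysis scripts.

One synthetic season stands in for the satellite-tag and reanalysis
downloads: ~30 over-sea flights departing near 71.3 N, a 6-hourly
six-level wind grid with temporally autocorrelated anomalies in which
only the 750 m level actually moves the birds, a tenth of flights
flying loops.  Every script loads (or creates) this world under
results/world/ so the whole pipeline runs off the same files.
"""

from pathlib import Path

from windtrack.synth import SynthConfig, write_world

ROOT = Path(__file__).resolve().parent.parent
WORLD_DIR = ROOT / "results" / "world"
RESULTS = ROOT / "results"

WORLD = SynthConfig(
    seed=42,
    n_tracks=30,
    heading_law="downwind",
    kappa=8.0,
    temporal_law="ar1",
    ar1_sigma=2.5,
    ar1_tau_h=24.0,
    level_decorrelate=True,
    loop_fraction=0.1,
    duration_h_range=(8.0, 16.0),
)


def ensure_world() -> dict:
    """Write the shared synthetic world if absent; return its file paths."""
    paths = {
        "tracks": WORLD_DIR / "tracks.csv",
        "wind": WORLD_DIR / "wind.nc",
        "station": WORLD_DIR / "station.csv",
        "coast": WORLD_DIR / "coast.geojson",
        "manifest": WORLD_DIR / "manifest.json",
    }
    if not all(p.exists() for p in paths.values()):
        write_world(WORLD, WORLD_DIR)
    RESULTS.mkdir(exist_ok=True)
    return paths
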
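# Methods

This note documents the models and procedures implemented in
`windtrack`, the choices made where the design was genuinely open, and
what the synthetic worlds do and do not establish.

## Geodesy

All distances, bearings and destination points are computed on a sphere
of radius 6,371,000 m (haversine inverse, closed-form forward).  At the
scales of the flights analysed here (up to a few thousand km) the
departure from an ellipsoid is below 0.5%, far inside every tolerance
used downstream, and it keeps the closed-form test oracles exact.  The
polar Lambert azimuthal equal-area projection (longitude origin
156.65° W) exists for map output only; no analysis runs in projected
coordinates, avoiding projection-induced distance distortion.  The
bearing between coincident points is undefined and returned as a `None`
sentinel, never a number.

## Wind fields and sampling

`WindGrid` holds eastward/northward wind components on a regular
(time × level × lat × lon) lattice: nominally 6-hourly and ~0.75°, with
six levels named by nominal height (10 m ground plus 100, 750, 1500,
2250, 3000 m a.s.l., mapped from the pressure levels 1000, 925, 850,
775 and 700 hPa).  Files in a [0, 360) longitude convention are
normalized to [−180, 180) on load; any missing cell is a hard load
error naming the variable and index — reanalysis extracts should be
complete, and silent filling would hide coverage bugs.

Spatial refinement (nominally 80 km → 10 km) is bicubic-spline
interpolation applied independently to u and v per time/level slice; it
reproduces polynomial fields up to cubic order exactly, which the tests
exploit as an oracle.

Trajectory sampling is nearest-neighbour in space and time.  Ties at
exact midpoints go to the earlier time slice and the lower grid index —
the data sources do not dictate a rule, so the package fixes one and
states it.  No temporal interpolation is applied by default: the
±6 h shift sensitivity check (`temporal_shift_sensitivity`) directly
measures whether the 6-h step is adequate for a given field (r close to
1 across levels), and an optional linear-in-time mode exists behind the
`time_mode` flag for fields where it is not.

## Track metrics

Summaries are computed on the over-ocean span of a track (first to last
ocean-labelled position); trailing over-land positions reflect
behaviour after landfall and are excluded.  Residency-area detection
beyond this ocean/land cut is out of scope; with real data the land
remainder between coast and settlement is typically small relative to
track length but is unmodelled here.

- Straightness = track length / geodesic departure–arrival distance
  (≥ 1; note this is the inverse of some literature conventions).
- Initial direction: segments are accumulated until cumulative length
  reaches 50 km, the crossing segment included in full, and the bearing
  of the accumulated displacement is taken.  "Mean over the first
  50 km" admits several readings; this one is simple and reproducible.
- Departure night: 12 h are subtracted from the local clock time
  (fixed UTC−8 offset, configurable) before taking the calendar date,
  so all birds leaving in one night share a departure day.
- Flight classes: loop if straightness ≥ 3.0, a threshold placed in the
  empty gap between observed directed flights (≤ ~2.3) and loop flights
  (≥ ~5.1), and configurable; otherwise directed-east when the final
  (departure→arrival) bearing has a positive eastward component,
  directed-west otherwise.  Real destinations are geographic regions;
  synthetic worlds have none, so the sign of the bearing stands in.

Selection filters (departure date before a cutoff, departure within
250 km of the origin, an over-ocean departure segment, track length
above 500 km) mirror the original study design; the analysis scripts
scale the length threshold to their shorter synthetic flights (100 km
for 8–16 h tracks) — a world-size choice, not a change of rule.

## Wind support, crosswind, air speed

For ground direction α and wind (u, v): `Ws = u·sin α + v·cos α`,
`Cw = |u·cos α − v·sin α|`, relative support `Ws/|wind|` (defined 0 in
calm air: no flow, no support), air speed = ground speed − Ws.  The
scalar air-speed definition is an approximation (the full wind triangle
would need heading data the tags cannot provide) and is used knowingly.
Wind is sampled at the segment start position and time (configurable to
midpoint); the underlying per-position convention is not determined by
the data, and the ±6 h sensitivity check bounds the consequences.

The hourly max-support altitude (`max_ws_altitude`) cuts a track into
consecutive 1-h windows anchored at departure (final partial window
included; the anchor is a package choice), picks per window the level
with the highest mean support (ties to the lower altitude), and
averages the winning window means.  Fixed-level track means use the
same window weighting so the max-support mean dominates every fixed
level by construction — an invariant the tests assert.

## Regression models

Speed models regress per-segment ground (or air) speed on wind support,
crosswind and their interaction, with a per-track random intercept
(statsmodels MixedLM, full ML so AIC is comparable across models
sharing a response).  The interaction term is included by default
because crosswind is expected to damp the wind-support effect; a flag
disables it.  Serial correlation within tracks is summarized by an
MA(1) coefficient computed from the pooled within-track lag-1 residual
autocorrelation (ρ = θ/(1+θ²) inverted); jointly estimating an MA(1)
residual structure inside a mixed model is not available in the Python
stack, so the coefficient is reported as a diagnostic rather than
absorbed into the likelihood.  When the mixed fit fails to converge
(common when the random-intercept variance is ≈ 0), the estimator
degrades to OLS with cluster-robust (by track) standard errors, and the
fit records which estimator ran; AIC is then the OLS likelihood with
its own parameter count.

Flight-altitude selection takes seven fits (six fixed levels + the
hourly max-support profile) on identical track/segment sets and returns
the argmin-AIC level, ties resolving to the lower altitude with fixed
levels before the profile.

The track-length model is OLS of track length (km) on mean wind support
over the first half of the track length, with a separate intercept per
flight class (classes with fewer than three tracks are dropped with a
warning).  The slope is reported in km per (m/s).

Direction models handle angles by unwrapping: each direction is reduced
to its deviation (wrapped to (−180°, 180°]) from its departure-night
circular mean before linear mixed-model fitting with a night random
intercept, and a Jammalamadaka–Sarma circular correlation is reported
alongside as a model-free diagnostic.  This linear-on-deviations
treatment is accurate while within-night dispersion is moderate and
degrades near ±180°, which the diagnostic exposes.

## Null models

`random_departures` shifts a track rigidly in time (spatial shape
fixed) to `n_sim` departures drawn uniformly in continuous time over
the season window (first to last departure); a night-grid mode that
preserves the observed time of day is selectable, since the sources do
not say whether draws respected nocturnal departure.  The statistic
(mean wind support over the first 50 km or over the full track) is
recomputed against the wind field for each draw.  Exceedance uses ≥,
so ties count against significance (conservative), and "significant"
means one-sided p < 0.05.  Seeded runs are bit-reproducible.

Delta wind support contrasts the support for a westward vs. an eastward
reference bearing from the departure site at 22:30 local time (the mean
departure hour); swapping bearings flips the sign exactly.  The
departure-shift profile evaluates support toward the actual destination
at ±12 h in hourly steps (ground-station series) and ±5 days in daily
steps (gridded wind, each level); offsets without coverage carry NaN
markers rather than failing.

## Shortest-route simulation

The counterfactual bird heads for the fixed arrival point, with the
bearing re-evaluated every 15-min step ("heading towards" a fixed point
is not a fixed compass bearing on a sphere).  Ground speed comes from
the fitted speed model's fixed effects only — the counterfactual bird
is population-generic; a flag can add a track's random intercept.
Negative predicted speed stalls the bird for that step (never moves it
backwards).  Arrival occurs when the remaining distance is within one
step-reach at the current speed, and the final step is clamped onto the
destination so routes never overshoot.  A hard cap of four times the
closed-form no-wind step count returns a `max-steps-exceeded` status
instead of looping; a route that never arrives has no defined flight
time, so the comparison reports NaN with the status rather than a
number.  Route comparisons are signed actual − shortest for both mean
wind support and flight time (positive time difference: the direct
route would have been faster).

## Synthetic worlds

`synth` generates the three data sources the pipeline needs — gridded
wind, an hourly ground station, a coastline — plus wind-coupled tracks,
with every latent value in a truth manifest.  The default world spans
three weeks at a 6-h step over an Arctic band (58–84° N), departures
near 71.3° N just off a zonal coastline, per-level mean winds of a few
m/s with AR(1) temporal anomalies (s.d. 2.5 m/s, correlation time
24 h, independent streams per level so altitude selection is
identifiable), air speed 11 ± 1 m/s, and flight durations of 8–16 h —
ground speeds and track lengths in the range reported for free-flying
shorebirds.  Movement kinematics are exact: each 15-min displacement is
the air vector plus the wind vector sampled with the same
nearest-in-space-and-time rule the annotation uses, so planted and
recovered wind agree bit-for-bit and, at calm crosswind, annotated
ground speed equals air speed + Ws identically.  Heading laws:
downwind-biased (von Mises around the departure wind direction),
fixed bearing (east/west), or goal-seeking; loop flights fly an
outbound leg and then steer to a point 60 km from the departure site.
Departure laws: uniform over the season window, or the
tailwind-peak slot of a random night (for power studies of the
randomization test).  All randomness flows from one seed; per-track
substreams derive from a stable hash of the track id.

What the worlds do *not* emulate: spatially structured storms, vertical
wind shear profiles, sea ice, behavioural responses (drift
compensation, grouping, air-speed adjustment to wind), or Argos
location error — the generator emits exact positions.  Passing tests
therefore establish that the pipeline's computations are correct and
its estimators calibrated under the stated statistical structure, not
that any biological conclusion transfers to real data.

## Problem sizes and numerical choices in the checks

The verification suite uses: 10,000 random draws for the vector
identities; 1,000 random tracks for the straightness bound; 200 seeded
replicates of an 80-track world (slope 22 km per m/s, residual s.d.
50 km) for track-length slope coverage against the analytic
2·SE band; 50 replicate worlds of 8 tracks for altitude selection
(≥ 90% must pick the planted 750 m level); 200 tracks across 8
independent wind realizations at 1,000 draws each for null calibration
(significance rate 5% ± 2% — independent realizations because
p-values of tracks sharing one weather history are dependent), plus a
50-track tailwind-timed world for power (≥ 90% significant); and
closed-form route-simulator checks (576 km at a predicted 16 m/s is
10 h ± one 15-min step).  These sizes are the package's verification
design; larger worlds change nothing qualitatively.

## Known limitations

- Sphere-only geodesy (adequate here; not for global-scale precision).
- The ocean/land cut stands in for residency-area detection.
- The MA(1) coefficient is diagnostic, not part of the fitted
  likelihood; AIC comparisons ignore residual autocorrelation beyond
  the random intercept.
- Direction models are linear on night-centred deviations, not fully
  circular regression.
- The speed model can predict negative ground speeds under strong
  headwinds; the simulator's stall rule handles this conservatively
  rather than modelling turning back.
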
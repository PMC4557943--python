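# scotowatch

Gaze-contingent scotoma-occlusion analysis of driving-hazard detection.

People with binocular central field loss (CFL) — a scotoma covering the
fovea, typically from macular degeneration — fixate with an extra-foveal
preferred retinal locus (PRL). In a driving simulator, pedestrians that
appear beside the road on a collision course stay at a nearly constant
eccentricity from the line of travel, so a scotoma *above or below* the PRL
is not expected to cover them. Yet vertical gaze movements (a glance at the
speedometer, an attempted foveation of a half-seen shape) can momentarily
drag a road-level hazard into the scotoma and delay the response.
`scotowatch` provides the full analysis pipeline for this question, for
researchers in low-vision psychophysics and driving safety:

* **visual fields** — binocular scotomas as convex polygons (≤100 vertices,
  PRL at the origin, degrees as planar chart coordinates), with perimetry
  pixel→degree conversion, scotoma size (mean of the cardinal chords through
  the centre), fixation stability, and gaze-tracking accuracy;
* **scene geometry** — constant-bearing pedestrian trajectories
  (lateral speed `v·tanθ`), angular projection of a 2-m pedestrian onto the
  driver's view, stopping distance `v²/2a`, and the timeliness criterion: a
  horn press is *timely* iff the car can stop before the pedestrian's
  crossing point at 5 m/s² deceleration;
* **occlusion scoring** — 60 Hz gaze merged onto the 30 Hz simulator
  stream, the pedestrian's vertical extent intersected with the
  gaze-centred scotoma at every sample, and occlusion time accumulated from
  appearance to the horn press;
* **statistics** — uncorrected Pearson χ² (2×2 and goodness-of-fit),
  Mann–Whitney U (0.5 per tie, min(U₁,U₂)), pooled/Welch t, Pearson r,
  log-RT regression with subject contrasts, untimely-reaction summaries,
  bootstrap median CIs;
* **synthetic studies** — a seeded generator producing drive logs, gaze
  logs (fixation jitter, dashboard glances, foveation slips, tracker
  dropout) and horn responses from a log-linear reaction-time model, so the
  whole pipeline is testable end to end and parameter recovery can be
  verified.

## Worked example

The packaged demo simulates two CFL participants (superior scotomas,
elevation +5..+15°) and two normally-sighted controls, each with 104
pedestrian appearances split over city (30 mph, appearing 220 ft away) and
highway (60 mph, 440 ft) drives:

```sh
scotowatch run --config examples/demo_config.yaml --out demo_out
```

This writes `events.csv` (one row per pedestrian appearance), `report.json`
and `manifest.json`. From `report.json`:

* median reaction time **2.33 s** (95% CI 2.20–2.40, n = 195) for the CFL
  group vs **1.07 s** (1.03–1.13, n = 205) for controls — the scotoma group
  responds about a second later;
* untimely reactions (car could no longer stop): **31.8%** of CFL
  detections vs **2.0%** of controls, concentrated on highway drives
  (29.7% vs 3.0% in the city);
* among gaze-usable events, occlusion time correlates with reaction time
  (r = 0.44), and the log-RT regression recovers an occlusion slope of
  0.43 log-s per occluded second (95% CI 0.26–0.61) against a programmed
  effect of 0.3;
* usable-gaze counts per eccentricity (76/67/69/71 of 104 each) show no
  availability bias (χ² = 0.63).

The same stages are available piecemeal: `scotowatch simulate` writes the
raw logs, `scotowatch score --drive … --gaze … --field … --out events.csv`
scores one drive, `scotowatch stats --events … --out report.json`
summarises an event table, and `scotowatch fixtures` regenerates the small
packaged demo data. Everything is importable from Python
(`scotowatch.occlusion.build_event_table`, `scotowatch.stats`, …).

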
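# Methods

This note records the models behind `scotowatch`, the conventions that pin
down every numeric result, and the limits of what the synthetic studies can
show.

## Visual-field model

The binocular visual field is a planar chart in degrees with the preferred
retinal locus (PRL) at the origin, azimuth positive rightward and elevation
positive upward. Degrees are treated as plane coordinates throughout (the
tangent-plane small-angle convention of perimetric charts); no spherical
correction is applied, which is accurate to well under 1% for the ±15°
region where all analyses happen.

Scotomas are convex polygons with 3–100 vertices, stored counter-clockwise;
a field holds zero or more polygons treated as a union (zero polygons is
the normal-vision control case). Convexity is validated by the sign of
every turn, and a reflex vertex is reported by index. Points on a polygon
boundary count as *inside* (closed-set convention); this one rule is used
consistently by chord computation, occlusion flags, and fixation-stability
counts.

* **Pixel→degree conversion** is the exact arctangent projection of the
  pixel offset from the screen centre at the viewing distance (default 1 m;
  screen y grows downward). The inverse is the tangent projection;
  round-trips are exact to ~1e-12°.
* **Vertical chord.** The intersection of a vertical line with a convex
  polygon is a single closed interval (possibly a point, possibly along a
  vertical edge). The implementation collects parametric edge crossings in
  a fully vectorised form; tests compare it against two independent
  oracles (shapely line intersection and dense point sampling).
* **Scotoma size** is the mean of the horizontal and vertical chords
  through the polygon's *vertex centroid* — the clinical "average diameter
  of the cardinal meridians", with the centre made explicit. A
  multi-polygon field reports the largest polygon's size (per-polygon
  sizes are also available); size is translation-invariant by
  construction.
* **Fixation stability** is the percentage of samples inside a circle of
  criterion diameter (2° or 4°) centred on the *sample centroid*, which is
  robust to a constant calibration offset; centring on the fixation target
  is available as an option and is the right choice when absolute accuracy
  is the question.
* **Gaze accuracy** is the mean planar Euclidean deviation from the
  intended gaze point, in degrees.

## Scene geometry and timeliness

Roads are straight; the car travels along +x, the driver's eye 1.2 m above
the road (a sedan-typical value, exposed in the config). A pedestrian event
is defined by a signed eccentricity θ ∈ {±4°, ±14°} and an appearance range
D = v·T with T = 5 s of travel time — 67 m / 220 ft at 30 mph (city), 134 m
/ 440 ft at 60 mph (highway).

The pedestrian appears on the line of sight at bearing θ (ahead `D·cosθ`,
lateral `D·sinθ`) and walks perpendicular to the road at the
constant-bearing speed `v·tanθ` (6.69 m/s ≈ 15 mph at 60 mph/14°), stopping
at the lane edge (1.8 m) and never entering the lane. With the car at
constant speed the bearing is constant until the stop, so the hazard stays
in one part of the visual field under steady forward gaze. The event window
runs from appearance to the earlier of T and the car passing the
pedestrian's station.

The pedestrian's image is a vertical segment: azimuth = bearing, elevations
`atan(−h_eye/range)` to `atan((2 − h_eye)/range)` for the 2-m figure.

A horn press at time t is **timely** iff the remaining distance to the
pedestrian's along-road station is at least the stopping distance
`v²/(2a)` at the instantaneous speed, with a = 5 m/s² (dry level road);
braking is assumed to start at the press, with no added motor lag, and the
boundary case counts as timely. With constant speed this criterion is
monotone: delaying a press can never restore timeliness.

## Occlusion scoring

Gaze logs (60 Hz, combined head+eye direction relative to car heading,
with validity flags) are merged onto the simulator stream (30 Hz) by
nearest-neighbour matching within half a gaze frame (±1/60 s) — for
phase-locked clocks this is exactly "every other gaze sample". A sample
with no valid gaze within tolerance is flagged gaze-missing.

At each sample the pedestrian segment is translated into visual-field
coordinates by subtracting the gaze direction (the PRL rides on the gaze
point), and the occluded fraction is the length of the segment covered by
the union of scotoma chords at that azimuth, over the segment height. A
sample is *occluded* when the fraction exceeds zero; occlusion time is the
occluded-sample count divided by the simulator rate, accumulated from
appearance up to (but excluding) the press sample, or through
disappearance when undetected. Gaze-missing samples count as not occluded,
a deliberate under-estimate.

Event-table assembly: a press is assigned to the earliest unanswered event
whose window contains it; detection means a press inside the window;
reaction time is press minus appearance; eccentricity is read off the
appearance bearing and classed small (|θ| ≤ 9°) or large. An event is
**gaze-usable** when at least 50% of its analysis-span samples carry valid
gaze — the availability threshold is a package convention, exposed in the
outcome columns (`n_samples`, `n_gaze_valid`) so other rules can be
applied. The availability check compares usable counts per eccentricity
against expectations proportional to appearance totals (a flat expectation
is available through the weights argument).

## Statistics

All statistics delegate to scipy/statsmodels with the conventions fixed
here: Pearson χ² without continuity correction (2×2 and goodness-of-fit);
Mann–Whitney U with 0.5 per tied pair, reported as min(U₁, U₂); two-sample
t in pooled (df = n₁+n₂−2) and Welch (Satterthwaite df) variants; natural
log for reaction times; subject indicator contrasts against the
alphabetically first participant in the log-RT regression; percentile
bootstrap (B = 2000, seeded) for median CIs; no multiple-testing
correction. Exact p-values for tied rank tests and mixed-effects models
are out of scope.

## Synthetic studies

The generator emulates the study design: per participant, 104 pedestrian
appearances evenly split over the four eccentricities and over one city
and one highway drive (one event per 8-s slot, constant-speed car). The
10×10-min drive schedule of the original protocol is condensed; nothing in
the scoring depends on inter-event content.

**Gaze** is a four-state process at 60 Hz:

1. forward fixation with isotropic Gaussian jitter (SD 0.5°);
2. dashboard glances: Poisson arrivals (default 3/min — a typical
   speedometer-check rate), duration ~N(0.7 s, 0.15 s), elevation −12°;
3. foveation slips: with probability 0.4 per event (scotoma carriers
   only), starting U(0.2, 0.5) s after appearance for a lognormal
   (median 0.5 s) duration, gaze shifts so the hazard lands at the scotoma
   centre — the eccentric-viewing failure mode in which attempting to
   "look at" a peripherally-sensed object hides it;
4. hazard pursuit: from ~0.25 s before the horn press, gaze tracks the
   pedestrian.

Tracker imperfection is i.i.d. per-sample dropout (2%) plus Poisson
multi-second gaps (8/min, mean 3 s), which yields usable-event rates
broadly comparable to gaze tracking of older low-vision participants.

**Responses** follow log RT = subject intercept + eccentricity-class
effect + `occ_slope`·(occlusion time) + N(0, σ), made self-consistent with
the occlusion actually experienced: the press lands on the first simulator
sample t with `exp(η + occ_slope·occluded-time-before-t) ≤ t`; events whose
predicted RT exceeds the window, or failing an independent
detection Bernoulli (p = 0.98), are undetected. The driver experiences the
dropout-free gaze; dropout only degrades the recorded logs. Default
intercepts put group medians near 2.3 s (CFL) and 1.1 s (controls), the
descriptive scale of the study population; `occ_slope` defaults to
0.3 log-s/s and the large-vs-small eccentricity effect to −0.12 log-s.

**Design for estimator consistency.** Occlusion measured from appearance
to press is intrinsically endogenous: any occlusion source that accrues
with elapsed time, or is truncated by the press, couples the covariate to
the outcome and biases the slope upward (a property the real analysis
design shares). The defaults therefore put most occlusion variance into
the event-locked early foveation slips, which complete before nearly all
presses and are independent of the response noise; the residual bias of
the recovered slope is ≈ +0.03 log-s/s at ~300 events. Parameter recovery
(`recover_parameters`) regresses log RT on occlusion time, eccentricity
class and subject over gaze-usable detected scotoma-group events and
reports the slope with its 95% CI; with no occlusion variance the slope is
flagged unidentifiable.

**Default scotoma.** The built-in synthetic field is a superior 16-gon
ellipse, azimuth ±8°, elevation +5° to +15°. The inferior edge sits well
above the PRL so that steady forward gaze leaves the road scene visible;
occlusion then arises from the modelled gaze behaviours rather than from
the pedestrian's image growing into the scotoma as the car closes in
(which would manufacture a reverse-causal occlusion–RT association). Very
late presses (final ~0.5 s of a window) can still incur this geometric
occlusion; it is real geometry, kept.

**What the synthetic studies do not show.** Gaze is piecewise-stationary
noise, not saccade kinematics; roads are straight with no traffic, turns
or lead cars; the response model has a single occlusion coefficient rather
than a perceptual detection process; scotoma shapes are symmetric
ellipses. Passing tests demonstrate that the pipeline's geometry,
bookkeeping and statistics are correct and that its estimator recovers a
known effect under the modelled conditions — not that real CFL gaze
behaviour is captured.

## Numerical conventions

Time is seconds from drive start (double precision); angles degrees;
distances metres internally, feet only at reporting boundaries. CSVs are
comma-separated UTF-8 with a header row and repr-precision floats, so
read→write→read round trips are exact. All random processes take explicit
seeds (mandatory in the generator); reruns are byte-identical. Chord and
fraction computations are exact interval arithmetic (no rasterisation);
the 0.01°-grid point-sampling oracle appears only in tests. Problem sizes
in the test suite (e.g. 20 replicates of a 3-participant × 104-event
recovery study; 1000 oracle comparisons) were chosen to keep the full
suite around half a minute while leaving the Monte-Carlo margins
comfortable.

## Known limitations

* The untimely criterion ignores brake-actuation latency and load-,
  surface- and tire-dependent deceleration; 5 m/s² is a fixed convention.
* The gaze-usable threshold (50% valid samples) is a package convention;
  the original analyses did not publish theirs.
* The availability χ² depends on the expectation model (appearance-total
  weights vs flat); both are provided, and they differ in the second
  decimal on realistic counts.
* Mann–Whitney p-values under heavy ties, repeated-measures ANOVA and
  stepwise logistic selection are intentionally absent.
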
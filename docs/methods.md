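# Methods

`daphtox` models a chip-based behavioral ecotoxicology workflow for
*Daphnia magna* neonates: an array of vertically mounted 13 × 8 × 2 mm
perfusion chambers (clusters of three sharing an inlet, 5 animals per
chamber) filmed as short back-illuminated video clips, from which
locomotory endpoints and acute immobilization dose-response curves are
derived. Because no public raw videos exist for such assays, the package
ships a first-class synthetic-data generator whose statistical structure
matches the assumptions of the analysis chain; every downstream stage is
validated against that generator's ground truth.

## Locomotion model (simulator)

Neonates swim in a hop-and-rest cycle: brief antenna-powered bursts
separated by passive rests during which the ~0.6 mm animal sediments.
The generator implements this as a marked Poisson process:

* Hop initiations occur at rate `hop_rate_hz` (exponential waits). Each
  hop displaces the animal by a truncated-normal length
  `N(hop_length_mm_mean, hop_length_mm_sd²)` (≥ 0) in a direction uniform
  in angle, with the vertical component pointing against gravity with
  probability `upward_bias`. The displacement is spread over
  `hop_duration_s`; if the next hop starts sooner, the displacement is
  completed in the shorter interval, so the expected active path per unit
  time is exactly `hop_rate_hz × hop_length_mm_mean` (sink drift
  excluded) — the closed form the test suite checks by Monte Carlo.
* Between hops the animal rests and sinks at `sink_speed_mm_s` until it
  reaches the chamber floor.
* Hops reflect specularly off the chamber walls. Wall behavior is not
  observable in the data this emulates; reflection is the simplest choice
  that conserves path length.

Defaults — hop rate 1 Hz, hop length 1.5 ± 0.5 mm, hop duration 0.2 s
(≈ 7.5 mm/s burst speed), sink speed 0.5 mm/s, upward bias 0.7 — produce
mm/s-scale population speeds and visually plausible hop-and-rest traces
at 30 fps. They are stand-in kinematics chosen once for realism, not
estimates of any particular culture; all are configurable.

Toxicant action has two channels. (1) *Immobilization*: each animal is
immobile with probability from a two-parameter Hill curve
`p(c) = cʰ/(EC50ʰ + cʰ)` (exactly 0.5 at the EC50). Immobilized animals
are rendered already settled in the bottom 10% band of the chamber —
clips are 30 s snapshots at hour-scale exposure times, long after a
sedimenting animal has reached the floor — and the draw is made once per
chamber, applied at every timepoint (no time-resolved immobilization
model). (2) *Behavior*: `activity_curve(c, t)` multiplies the hop rate
(< 1 hypoactivity, > 1 hyperactivity) after an onset lag.

Rendering draws each animal as a dark 2:1 ellipse (major axis = body
length) on a light background with a dark wall border, Gaussian blur
(default 1 px) and additive Gaussian noise (default SD 2 on the 0–255
scale). The default canvas maps the 13 mm chamber length to 512 px
(mm/px ≈ 0.0254) rather than emulating a full 2048² sensor; calibration
carries the physics. The 2 mm chamber depth is not rendered (the
analysis is strictly 2-D). Animal–animal collisions and occlusions are
*not* prevented — overlapping renders are a deliberate tracker stress
case. For benchmarks that require guaranteed separation
(`sample_separated_trajectories`), each animal is confined to its own
horizontal lane with a margin; free motion of five animals in a
13 × 8 mm chamber cannot stay non-overlapping for a whole clip.

Ground truth records, per animal and frame: position, behavioral phase
(hopping / resting / immobile), and the exact active swim path
(`swim_distance_mm`), which the sampled polyline slightly underestimates
where hops bend off walls.

## Detection

Per-pixel temporal median over the clip estimates the static background
(moving animals occupy any pixel in a minority of frames). Foreground is
`background − frame > threshold`; the default threshold is 5× the noise
SD estimated robustly (1.4826 × MAD) from background-subtracted pixels,
so no manual threshold is needed. Connected components (8-connectivity)
with area in 0.25–4× the expected animal area (ellipse of the configured
body length) become detections — the lower gate rejects specks, the
upper keeps touching pairs. Centroids are intensity-weighted (sub-pixel
stability under blur), and detections are sorted by (x, y) for
determinism.

## Tracking

Per frame, live tracks are matched to detections by the Hungarian
algorithm on squared distance, with matches beyond
`gate_mm × (1 + missed frames)` forbidden (gate default 4.5 mm = 3 hop
lengths per frame interval). Unmatched detections open tracks; tracks
undetected for more than `max_gap_frames` (default 3) close; shorter
gaps are bridged by linear interpolation with a per-sample flag; tracks
under `min_track_frames` (default 15) are dropped. There is no motion
model: constant-position prediction suits hop-and-rest motion better
than constant-velocity extrapolation, which overshoots during rests.
Identity swaps at close encounters are tolerated for endpoint purposes —
endpoints average over the chamber population — but are measured by
`evaluate_tracking` (swap count, truth-matched fraction within one body
length, absolute chamber distance error), which reproduces the
qualitative density effect: identity errors grow from 2 to 10 animals
per chamber.

## Endpoints

Per track: total distance (sum of frame-to-frame displacements), mean
speed (distance/duration), mean absolute acceleration (finite
differences of step speeds). Steps below a jitter floor are zeroed. The
floor is expressed as a speed, 1.5 mm/s, converted to a per-step
threshold of `1.5/fps` mm (0.05 mm per step at the standard 30 fps).
A fixed per-step floor would make the distance endpoint depend on the
sampling rate, and at 10 fps would sit exactly on the default
sedimentation step (0.5 mm/s / 10 fps = 0.05 mm); the speed form keeps
the metric fps-invariant and keeps passive sinking excluded, matching
the generator's closed-form expectation. Note the floor is a hard
threshold on Rayleigh-distributed noise steps: noise with per-axis SD a
third of the floor still leaks a small tail of steps past it, so
"distance ≈ 0" for a stationary noisy track strictly requires noise well
below floor/3 (the suite tests both regimes).

Per chamber: per-animal metrics averaged over the population. When the
number of loaded animals is known it is the divisor for the summed track
distance, so a tracker that fragments one animal into two tracks does
not bias the population mean. `frac_active` is the fraction of animals
covering more than two body lengths in a clip (the "active organism"
endpoint needs an operational cutoff; two body lengths separates real
relocation from in-place jitter). Non-motility is the imaging analog of
the 10 s prodding criterion: positional extent below 0.3 mm in every
sliding 10 s window *and* mean position in the bottom 10% band
(a sedimented, unresponsive animal).

Treated chambers are normalized to concurrent controls per timepoint as
`100 × (treated − control)/control` from replicate chamber means, with a
two-sample t-test on the replicate values; replicate controls differing
by ≥ 5% trigger a consistency warning. Syndrome labels: *cessation* at
≤ −80% at the first post-exposure timepoint (takes precedence);
*hyperactivity* at ≥ +20% with p < 0.05 within hours 1–8;
*hypoactivity* at ≤ −20% with p < 0.05 (the −20% cutoff mirrors the
+20% hyperactivity definition). Acceleration is reported but carries no
classification weight.

## Dose-response

Immobilization counts are fitted by binomial maximum likelihood to the
two-parameter Hill model, optimized on (log EC50, log h) with
Nelder-Mead from three deterministic starts (slopes 0.7/2/5 around an
interpolated half-response concentration); the two-parameter form (floor
0, ceiling 1) is appropriate because immobilization is a fraction, and a
four-parameter variant is exposed for continuous behavioral metrics.
A weighted least-squares mode exists for comparison with fraction-based
fits. Control rows carry no information under this model and are
excluded; Abbott's correction `(p − p₀)/(1 − p₀)` (clipped at 0) is
available but off by default, with a QC flag when control mortality
exceeds 5%. ECx follows in closed form,
`ECx = EC50 (x/(100−x))^{1/h}`. EC50 confidence intervals come from a
stratified nonparametric bootstrap (resampling replicate rows within
each concentration, percentile interval, flagged unreliable if > 20% of
resamples fail); with only a few replicate rows the percentile interval
undercovers somewhat, a known small-sample property the coverage test
acknowledges. `compare_methods` reports the Pearson r, R² and
least-squares line between paired chip/reference assays, and
`behavioural_stats` runs the per-timepoint one-way ANOVA plus
independent t-tests of each concentration against the concurrent
control (unadjusted by default; Holm optional). Groups with identical
values return p = 1 rather than the NaN a variance-ratio test would
produce.

## Mass transfer

Each chamber in a cluster of three is treated as a well-mixed
compartment (CSTR) in series: `dCᵢ/dt = (Q/Vᵢ)(Cᵢ₋₁ − Cᵢ)`, C₀ = 1.
With equal volumes the k-th breakthrough is the Erlang-k CDF; the ODE
path must agree with the closed form to < 1e−6 and both are exposed.
Defaults: 208 µL per chamber (13 × 8 × 2 mm) and 5 mL/h, giving
τ = 2.50 min and 95% exchange at 7.48 / 11.84 / 15.71 min for chambers
1–3 — the observed minutes-scale ordering with a common dye-exchange
time of ~15 min for the full series. "Complete exchange" is
operationalized at 95%, the cutoff that best matches the observed times
at this geometry. The idealization neglects connecting-channel volume
and in-chamber velocity gradients (per-cluster flow is assumed; a chip
routing the 5 mL/h over several clusters in parallel would scale all
times by the number of clusters). It reproduces exchange timescales,
not velocity or pressure fields.

## Problem sizes and numerical choices

* Desk-scale defaults throughout: 512-px chamber renderings; EC50
  recovery experiments use 200 simulated assays per toxicant (7
  log-spaced concentrations bracketing the target, n = 15 per
  concentration, slope 2); the full-pipeline behavioral experiment uses
  15 s clips at 10 fps, 5 animals per chamber, 50 paired
  control/treated seeds.
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; datasets, pixel data and analyses are bit-reproducible per
  seed.
* Hill probabilities and curves are evaluated as logistics in
  log-concentration (no overflow at extreme ratios); probabilities are
  clipped at 1e−10 inside the likelihood.
* Degenerate inputs are first-class: zero hop rate (pure sedimentation),
  zero flow (no washout), empty chambers (invalid endpoint record with a
  logged warning), all-or-nothing response tables (rejected with advice
  to widen the concentration range).

## What passing tests do and do not show

The generator emulates the *statistical* structure the pipeline assumes:
Poissonian hop-and-rest kinematics, Hill-distributed immobilization,
dark-ellipse imaging with Gaussian noise. It does not emulate real
optics (shading, refraction at chamber walls, animal appearance change
with orientation), animal–animal interactions, flow-coupled drift, or
time-resolved immobilization dynamics. Recovery of generative effect
sizes through the full video pipeline therefore demonstrates that the
detection → tracking → endpoint → statistics chain is unbiased and
correctly calibrated under its stated assumptions — not that those
assumptions hold for any particular laboratory's imagery.

## Known limitations

* 2-D analysis only; out-of-plane motion in the 2 mm depth is ignored.
* The tracker has no appearance model; prolonged occlusions at high
  density fragment tracks (measured, and mitigated at the population
  level by dividing by the known animal count).
* The sampled-polyline path length underestimates the true path by a few
  percent where hops reflect off walls at 30 fps; the exact generative
  swim distance is recorded alongside for oracle use.
* Percentile bootstrap EC50 intervals undercover with ≤ 3 replicates.
* Chamber volumes (208 µL each) imply a larger total than a single
  shared-flow chip volume would suggest; the washout model assumes the
  full 5 mL/h perfuses each cluster.
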
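# Methods

## Model overview

`fusionpace` simulates steady-state ventricular activation in LBBB patients
under CRT device programming. The chain is:

1. **Cohort synthesis** — virtual patients with PR interval and native VAT
   drawn from truncated normals.
2. **Conduction graph** — a per-patient biventricular surrogate anatomy with
   region (septum / LV free wall / RV free wall) and layer (endo / epi) tags.
3. **Calibration** — a single velocity multiplier per patient, found by
   bisection, so the intrinsic activation span matches the patient's native
   VAT.
4. **Device timing** — fixed AV-delay modes and the dynamic negative-AV-
   hysteresis state machine produce a per-beat pacing schedule.
5. **Wavefront engine** — the beat's activation map is the pointwise-minimum
   arrival over intrinsic and paced sources, by multi-source Dijkstra on the
   graph.
6. **Metrics and statistics** — VAT (max − min activation time, the QRS
   proxy), breakthrough sites, and paired-t comparisons across the 14-mode
   protocol.

## Cohort generator

Defaults are the reference trial's baseline distribution: n = 14, PR
189.0 ± 36.1 ms, native VAT (QRS duration) 181.6 ± 23.9 ms. PR and VAT are
independent truncated normals — only marginal moments are available, so the
simplest consistent joint is used. Truncations, by rejection sampling
(cap 10 000 draws):

- PR ≤ 250 ms — the trial's inclusion bound for preserved AV conduction.
- PR ≥ 120 ms — lower limit of normal AV conduction. Without it the
  unbounded tail occasionally produces PR ≈ 105–110 ms; such a patient's
  AVI falls below the nominal sensed AV delay (120 ms), fixed-delay pacing
  is inhibited on every beat, and the patient cannot be measured in all
  configurations — a patient type the protocol could not have enrolled.
- native VAT ≥ 130 ms — an LBBB floor (conventional broad-QRS criterion);
  the source population reports LBBB without stating a threshold.

Atrial sense latency (P-wave onset to the device's atrial sensed event)
defaults to 30 ms; it separates the device AVI scale from the surface PR
scale. Age/sex/etiology are carried as annotation only and have no
electrical effect. Per-patient RNG substreams are
`default_rng([rng_seed, patient_index])`, so a cohort of k is a prefix of a
cohort of n > k under the same seed.

## Surrogate anatomy

Image-derived meshes are out of scope; the geometry is the simplest shape
that preserves the topology the metrics need. The LV is a two-layer prolate
ellipsoidal shell (endo semi-axes 30/45 mm, wall 9 mm), open above
z = 0.35·c (basal cut), apex at −z. Its sector facing +x (±55°) is tagged
septum. The RV is a two-layer crescent shell (semi-axes 42/61 mm, wall
4 mm) wrapped around the septal sector (±80°) and attached to the septal
RV-facing surface along its boundary — the surrogate interventricular
grooves. Node spacing defaults to 3 mm (clinical activation-mapping
resolution is 2–4 mm; values outside warn). Edges connect nodes within
1.6× spacing inside each shell, each endo node to its nearest epi node
transmurally, and crescent-boundary nodes to the nearest septal surface
node.

Conduction is isotropic: edge traversal time = length / velocity. Working
myocardium conducts at 0.5 mm/ms. RV endocardial edges form a fast layer at
2.0 mm/ms — the surrogate right-sided Purkinje network. The LV endocardium
has **no** fast layer: that *is* the LBBB lesion. Intrinsic activation
enters at three RV endocardial breakout nodes at the basal anterior septal
margin (the right-bundle insertion), firing at the patient's PR interval.

Free geometric constants (radii, elongations, basal cut, sector angles,
breakout placement) were fixed once so that the default anatomy meets two
physiological anchors of an LBBB heart: an uncalibrated intrinsic span near
180 ms, and a breakout-to-RV-apex conduction time near 22 % of that span
(≈ 40 ms after calibration), matching reported RV electrogram sensing
delays relative to QRS onset in LBBB. These constants are deliberately not
per-patient parameters; patient variation enters through the calibration
multiplier (and optionally `anatomy_scale`).

## Calibration

A single multiplier m scales every edge time; shortest-path arrival
differences are homogeneous in m, so intrinsic VAT is strictly increasing
in m and bisection on m ∈ [0.1, 10] converges in ≤ 60 iterations to |VAT −
target| ≤ 1 ms (tolerance configurable). Targets outside the achievable
range raise rather than clamp.

## Device model

- AVI = intrinsic arrival at the RV lead − atrial sense latency. With the
  default anatomy the AVI runs ≈ 10 ms above the surface PR (40 ms RV-lead
  delay minus 30 ms atrial latency).
- Fixed modes (RV-only, biventricular) pace at the sensed AV delay
  (120 ms); all atrial events are sensed (sinus rhythm), so the paced AV
  delay (170 ms) is retained but unused. If the scheduled stimulus would
  land at or after intrinsic arrival at the RV lead, the beat is inhibited.
- Dynamic fusion modes: measurement beats open each 256-beat cycle (3
  beats, AV delay extended to the last AVI estimate + 100 ms so they
  conduct); the three observations are averaged (mean; median/last
  configurable — the physical device's summary statistic is unpublished)
  and the paced AV delay becomes max(AVI − offset, 30 ms floor); clamping
  is flagged in the beat log. VV interval is fixed at 0 (simultaneous
  leads); pacing latency is 0 (config knob).
- Heart rate only paces the log's realism; maps depend on intra-beat
  intervals alone.
- One representative steady-state beat per mode is mapped (the last
  non-measurement beat after a full cycle).

## Why a U-shaped offset response emerges

Let δ be the intrinsic conduction time from breakout to the RV lead
(≈ 40 ms calibrated). Pacing fires at `latency + AVI − offset
= PR + δ − offset`, so `offset − δ` is exactly the lead of the stimuli over
the intrinsic breakout. For offset < δ the stimuli trail intrinsic
conduction and VAT rises toward native; for offset > δ intrinsic conduction
contributes less and VAT rises toward the pure-paced (biventricular) level;
the per-patient minimum sits at offset ≈ δ. Because δ scales with the
calibration multiplier, per-patient optima spread over ≈ 30–50 ms across
the cohort, and the cohort-mean curve has its argmin there — the mechanism
behind the reported 30–50 ms optimum band, reproduced here rather than
assumed.

## Statistics

Paired two-sided t-tests (scipy), 95% CI = mean ± t₀.₉₇₅,ₙ₋₁·SD/√n on the
per-patient differences; the paired-mean identity (mean of differences =
difference of means) holds to machine precision and is tested. Zero-variance
differences are flagged degenerate. No multiple-testing correction is
applied, matching the reporting convention of the study design simulated.
Report rounding is 1 decimal; computation is full precision.

## Problem sizes and determinism

Default graphs have ≈ 5 000 nodes / 19 000 edges (3 mm spacing); a full
14-patient × 14-mode study, including calibration, runs in a few seconds on
one core. All randomness flows from a single integer seed; cohorts, studies
and exports are pure functions of (config, seed).

## What the generator does and does not emulate

It reproduces the marginal PR / QRS distribution, inclusion bounds, and the
LBBB activation sequence. It does **not** model scar or ischemic substrate
(50 % of the reference population), anisotropy or fiber orientation,
PR–QRS correlation, repolarization, body-surface ECG synthesis, or the
imaging inverse problem — activation maps are the simulator's ground truth.
Passing tests therefore demonstrate the timing mechanism and the statistics
pipeline under idealized conduction, not clinical accuracy of absolute VAT
values; notably, paced propagation here uses the same edge velocities as
intrinsic conduction (paced wavefronts entering the RV fast layer spread
fast), which makes simulated biventricular pacing more effective relative
to native conduction than observed in patients, and leaves RV-only pacing
near native rather than clearly below it. Arrival-time *differences* across
modes — the study's comparisons — are the quantities the model is built to
rank correctly.

## Numerical conventions

Coordinates in mm (right-handed, apex −z, RV +x); times in ms. Nearest-node
selections (leads, breakout) break ties by lowest node id; so do earliest-
breakthrough queries. Wavefront ties need no rule (pointwise min is
symmetric). Degenerate inputs raise: empty source lists, unknown leads,
disconnected graphs, < 100-node anatomies, infeasible sampling or
calibration targets.
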
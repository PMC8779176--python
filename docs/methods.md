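# Methods

This note documents the models, parameter choices and numerical decisions
behind `trichamber`, in the order the pipeline runs.

## Arena geometry and zone model

The arena is a square of `arena_cm` = 100 cm, rendered in pixels at
`px_per_cm` = 3 (so 300 × 300 px). Coordinates follow the image
convention: origin top-left, y down, so the enclosure corners are at large
y. The three chambers are exact thirds of the width; the published
"approximately 33 cm" is realized as 33.33 cm so that the five scoring
zones tile the arena with no gap or overlap — a requirement for the
conservation property that per-zone times sum to the trial duration.
Each internal wall carries a 10 × 11 cm door rectangle centered at
mid-height; door area is attributed to the center chamber, because doors
open from the center and the source protocol is silent on the point.
Investigation zones are the bottom thirds of the flanking chambers
(33.33 × 33.33 cm squares, matching the published "approximately
33 × 33 cm"); each contains a 15 cm-wide cylindrical stimulus enclosure in
the outer corner.

Neither the video frame rate nor the pixel calibration of the original
recordings is published. The defaults are reverse-engineered from two
printed facts: "200 ms ≈ 7 frames" implies ≈35 Hz, and a 7.5 px contact
threshold next to a ≈5 px rat nose suggests a coarse scale for which
3 px/cm (making 7.5 px = 2.5 cm) is a plausible choice. Both are
configurable; they are assumptions, not facts about the original videos.

## Zone assignment (the 80 % rule)

The original tracker scored entry when 80 % of the animal's blob area was
inside a zone. Keypoints carry no blob, so the closest computable analog
is used: the convex hull of the 8 experimental-animal keypoints. A frame's
label is the zone containing ≥ 80 % of hull area (exact polygon clipping
via Shapely); if no zone reaches 80 % — the hull straddles a wall — the
previous frame's label persists. This hysteresis prevents label flicker at
boundaries and matches the "enter an area" semantics; the first frame
falls back to the body-center's zone, as do degenerate hulls (fewer than
three distinct points). There is no minimum visit duration: single-frame
visits count. For speed, frames whose 8 points unanimously classify into
one rectangular zone skip the polygon clipping; frames near doors or walls
take the exact path.

## Distance traveled

Sum of body-center Euclidean displacements, converted px → cm → m.
Frames with body-center likelihood < 0.90 are linearly interpolated before
summation (bridging), so a tracking dropout does not register as a teleport
spike; a trial with no usable body-center frames reports missing.

## Nose-touch detection

Per frame and per enclosure, the Euclidean distance between the
experimental nose and that enclosure's stimulus nose. A frame is *valid*
for a target only when both noses have likelihood ≥ `confidence_floor`
(0.90). A contact frame is valid with distance strictly below
`distance_threshold_px` (7.5) — "below a threshold" is read literally as
a strict inequality. Contact frames are grouped into maximal runs
(run-length encoding); runs of at least
`ceil(min_duration_ms / 1000 × frame_rate)` frames become bouts, so the
bout always covers at least the stated milliseconds. Invalid frames are
non-contact and therefore *break* runs: "consecutive frames" is literal
and no gap-bridging is applied. Whether the original criterion was applied
in frames or milliseconds differs by at most one frame at any plausible
frame rate; both views are exposed through `frame_rate` plus the ceil
rule.

Calibration against human-scored bout lists is an exhaustive grid search
(distance 2–15 px in 0.5 px steps; durations from ≈57 to 500 ms in steps
of one frame period) minimising the RMSE of per-trial *total* nose-touch
time — the only seconds-scale quantity consistent with published
scorer-variability values of 3.5–5 s. Ties are broken toward the larger
distance, then the larger duration: among equally good fits the most
conservative (least fragmentary) rule wins, and the tie-break is exercised
by fixtures containing a minimum-length bout and near-threshold approach
frames, which make the optimum unique.

## Trial QC

Three quantitative rules replace the original visual occupancy-plot
inspection, preserving its thresholds: (1) more than 20 s (strict) of
lost body-center tracking excludes the trial; (2) less than 10 s
(inclusive) in either *whole* flanking chamber during stage 1 keeps the
trial for stage 1 but removes the animal from stage 2 — the wording
"flanking chamber" is taken to mean investigation plus distal zone;
(3) distance-traveled outliers within sex (median/MAD z, SD fallback at
zero MAD, default |z| > 4) are flagged for review but not auto-excluded,
since the original step was a human check. Exclusions not derivable from
tracks (escaped animals, incomplete habituation) enter as a manifest-level
`manual_exclude` flag. Applying exclusions is idempotent and every removed
row is logged with its rule.

## Statistics

Sex differences use the two-group Kruskal–Wallis test on raw values — the
published choice for metrics that fail Shapiro–Wilk/Bartlett checks — with
classical pooled-SD Cohen's *d*, sign convention F − M. The assumption
checks are computed and reported but advisory: the pipeline proceeds
regardless, as the rank test and transform are the designed response.

Treatment effects are one-way fixed-effects ANOVAs within sex (per
generation × lineage × metric), on Box–Cox-transformed values. One lambda
per metric is fit by maximum likelihood on the pooled values and applied
identically to every cell ("separately but equally"); metrics with zeros
are offset by half the smallest positive value before transforming, with
the offset recorded. Welch correction is not applied; tests are two-sided
at α = 0.05. Effect size is partial eta squared
SS_t / (SS_t + SS_e), labelled small/medium/large at 0.01/0.09/0.25.
Tukey HSD (studentized range, Tukey–Kramer for unequal n, via
`scipy.stats.tukey_hsd`) runs only when the omnibus test is significant;
no additional familywise correction is applied across metrics or cells.
F, p and eta are computed from explicit sums of squares (needed for eta
anyway) and cross-checked in the tests against `scipy.stats.f_oneway` and
`statsmodels`' Tukey implementation.

A note on score averaging: summary scores computed per animal then
averaged differ in the third decimal from the ratio of the mean times;
the pipeline computes per-animal scores and averages them.

## Synthetic trials: what is emulated

The simulator generates the *statistical structure* the analysis assumes,
not realistic rat kinematics:

* the body center performs a zone-structured walk — exponential dwells
  (configurable mean per zone), straight transits through door waypoints
  at `step_speed_cm_s`, waypoint wander within a zone;
* the other body parts ride a rigid ~16 cm template oriented along the
  heading with ~0.25 cm jitter; stimulus noses jitter smoothly within
  their enclosures (the empty enclosure in sociability emits
  low-confidence noise, as a pose network does for an absent animal);
* planted nose-touch bouts are appointments: the walk arrives in time, a
  3-frame ramp sweeps the inter-nose distance down through 1.6×/1.3×/1.05×
  the threshold, bout frames hold it at 0.3–0.9× threshold, and a guard
  keeps every other frame at ≥ 1.5× threshold — so recall and precision
  of the detector at the planted thresholds are exactly 1, and calibration
  is identifiable;
* confidence dropouts (< 0.90) and single-frame teleport glitches occur at
  configurable per-frame rates, with the three nose keypoints protected
  during planted bouts so the plants stay verifiable;
* the ground-truth zone timeline applies the same 80 %-hull rule as the
  scorer (sharing only the low-level area-fraction primitive): a
  body-center-crossing definition would disagree with any area-based
  scorer by many frames per transition simply because the hull is long.

Cohort simulation draws per-animal metric targets from normal
distributions anchored to the published per-sex summary table
(SD = SEM·√N at N ≈ 600/sex), scaled linearly for shorter trial
durations, then inverse-tunes dwell means, transition bias, speed and
planted bouts per trial. Standardized effects (`d` × pooled anchor SD)
shift the targets of matching design cells; a sex-effect spec replaces the
baseline sex gap with the requested one. Score-type metrics are drawn
directly and the component times derived from them, which keeps planted
effect sizes on scores interpretable. Nose-touch bouts are clustered
(several touches per enclosure visit, cluster size 1 + Poisson(2.5)) and
capped against the invest-time and visit budgets; at full 600 s duration
the realized nose-touch totals reach roughly half their targets because
occupancy fidelity is given priority over contact-time fidelity.
Realized preference/novelty scores land within ≈0.1 of their targets
(median), which is the fidelity the pipeline tests require; per-animal
statistical tests operate on the drawn target tables, where effects are
exact by construction.

What passing tests on synthetic data do **not** show: robustness to real
pose-estimation failure modes (identity swaps, partial occlusion by the
enclosure, systematic nose-position bias near the bars), to non-exponential
dwell structure, or to correlated metric noise across phases.

## Problem sizes and runtimes

The test suite simulates seconds-to-minutes-scale trials (30–120 s at
35 Hz; one 26 000 s low-rate trial for dwell convergence), 1000-replicate
null calibrations for the ANOVA, 40 replicate cohorts at n = 20/group for
the planted-effect power check, and a full default-grid calibration over
three 90 s trials; the whole suite runs in about half a minute on one
core. These sizes were chosen as the smallest that make the statistical
assertions stable.

## Known limitations

* The hull-area analog of the 80 % rule is not identical to the original
  tracker's blob-area rule; the blob is wider than the keypoint hull, so
  boundary labels can differ near walls.
* Door placement and geometry at mid-wall are an assumption; the original
  figure shows doors but not their positions.
* The simulator's planted-bout scheduler cannot honor bouts that start
  before the animal can physically reach the enclosure, bouts closer than
  about one cross-arena transit for different targets, or any bout during
  habituation; it raises instead of silently adjusting.
* Litter is carried as metadata but not modelled as a random effect,
  matching the original fixed-effects analysis.
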
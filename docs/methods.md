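# Methods

This note records the models, parameter choices and known limitations behind
`limbwear`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sensor model and clocks

Two independent monitors are assumed: a tri-axial accelerometer at the
prosthetic wrist (50 Hz, ±16 g full scale) and a thigh-worn activity monitor
whose vendor software exports one row per 60-s epoch with seconds per
activity class and a step count.  All timestamps are timezone-naive local
wall time: every daily summary is defined midnight-to-midnight on the local
clock, so local time *is* the analysis clock.  The two monitors' internal
clocks may disagree; a bench-assessed offset (thigh minus wrist, seconds) is
applied from configuration in `fusion.align_streams`.  An advisory
cross-correlation estimator (`estimate_clock_offset`) reports the apparent
lag between wrist counts and thigh steps but is never applied silently.

## Activity-count emulation

Counts are produced per axis by the classic on-board chain of legacy
research accelerometers: resample to 30 Hz (linear interpolation),
band-pass filter, decimate to 10 Hz, clip to ±2.13 g, rectify, zero
everything below the 0.068 g dead-band, quantize at 0.0164 g per unit,
accumulate 1-s bins and sum them into 60-s epochs anchored to whole minutes
of the local clock (a partial trailing epoch is discarded).  The per-epoch
vector magnitude is the unrounded Euclidean norm of the three axis counts.

The band-pass is an order-3 Butterworth over the 0.29–1.66 Hz movement
band at 30 Hz, peak-normalised to 0.965, frozen as literal coefficients in
`counts.py` so the chain does not depend on any filter-design routine at
run time.  This is a replication of the legacy device's published passband,
not a system-identified copy of its analogue electronics; absolute count
magnitudes will therefore differ somewhat from a physical device.  Every
downstream use in this package reads counts only through the non-wear
detector's zero/spike thresholds, which are insensitive to in-band gain.

Numerical choices: the IIR filter is initialised at its steady state for
the first input sample (`lfilter_zi`), because a zero-state start turns the
1 g gravity offset into a start-up transient and hence phantom counts in
the first epoch.  Resampling is linear interpolation, which is exact for
the piecewise-linear test signals and deterministic.

## Non-wear / wear detection

An epoch is non-wear (prosthesis doffed) iff it is covered by some window
that (a) starts and ends on epochs with `vm ≤ zero_threshold` (default 0
counts), (b) spans at least `min_nonwear_run` minutes (default 60), and
(c) contains at most `spike_tolerance_epochs` (default 2) interrupting
epochs, each with `vm ≤ spike_max_vm` (default 100 counts) and no two of
them adjacent.  The window-cover formulation is order-independent — the
result does not depend on a scan direction — and is implemented by
run-length-encoding chains; the test suite checks it against a brute-force
per-start enumeration on randomized sequences.  The spike allowance absorbs
brief artefactual movements of an unworn prosthesis (being moved, knocked)
without splitting a long non-wear run; the 60-min floor keeps still wearing
(reading, resting) from masquerading as non-wear.  Defaults are exposed in
`NonWearParams` for sensitivity analyses.

Don/doff events are the doffed→worn and worn→doffed transitions.  Segment
boundaries (recording start/end, data gaps) emit no events: a behaviour
window attached to an artefactual boundary would bias the fused summaries.
Daily wear hours are reported for every day together with observed hours,
so the caller can apply any valid-day rule; group averages in this package
default to the same >20 h rule used for the thigh stream.

## Thigh-stream analysis

*Dominant label*: the class with maximal seconds per epoch; ties are broken
by a fixed priority (stepping > cycling > upright > seated transport >
sedentary > secondary lying > primary lying > non-wear).  Ties are
essentially measure-zero in real exports; the priority exists so the
pipeline is deterministic.

*Stepping bouts*: minute epochs cannot represent exact continuity, so a
bout core is a maximal run of epochs each with ≥ 55 s of stepping, extended
by immediately adjacent partial epochs (0 < stepping < 55 s) which a walk
starting mid-epoch necessarily produces; a partial epoch wedged between two
cores joins neither, since the embedded pause breaks continuity.  Bout
duration is the summed stepping seconds.

*Transitions*: a bout qualifies as movement between environments when its
duration exceeds 60 s, or — when a heading series is attached — when some
sub-segment of at least 25 s turns no more than 30° in total.  The 30°
straightness bound is this package's choice (exposed in configuration,
excluded from acceptance checks): walking for 25 s in a near-straight line
is implausible inside a dwelling, and 30° tolerates sensor noise without
admitting corridor-scale turns.

*Sleep*: runs of dominant primary-lying epochs, merging interruptions of up
to 15 min (toilet breaks), kept when at least 3 h long.  Only the main
nightly sleep anchors the home/away day; daytime naps are not anchors.

*Home/away*: each day's waking window runs from the end of the morning
sleep to the start of the evening sleep.  The leaving/returning anchors
(first transition after sleep, last before sleep) alone cannot represent
multiple daily excursions, so the default model toggles home↔away at every
transition, with the anchors enforced: an odd transition count closes the
final away interval at the returning anchor.  An `anchors` mode reports the
first→last transition span instead ("active hours"), since either reading
of a daily "time away" figure is defensible; both are provided.  Days
without a sleep anchor are excluded with an explicit reason.  Observed
hours count monitor-on-body time (epochs present minus their non-wear
seconds); a day is valid iff observed hours exceed 20.

## Fusion

Events and behaviour epochs are compared on the wrist grid.  For each event
at time *t*, stepping epochs are counted in [*t*−30 min, *t*) and
[*t*, *t*+30 min); an epoch "counts" if it contains any stepping seconds
(default), or if stepping is dominant (sensitivity mode).  A window is
complete only when every epoch on both sides exists, contains no monitor
non-wear, lies inside the aligned overlap, and no other event falls within
it; incomplete windows are flagged and excluded from group means — the
conservative reading of a fixed 30-min design.  Group summaries average
participant means with equal participant weight; empty group × phase ×
event-kind cells are reported as missing, never zero.

## Synthetic cohort generator

The generator emulates the behavioural structure the analysis assumes, not
any particular recorded dataset.  Per participant-day: one overnight sleep
(onset 22:30 ± 25 min, 8 h ± 25 min); a Poisson(2) number of away
excursions of 45–240 min (mean ≈ 100), separated by ≥ 125 min; prosthesis
wear locked to excursions with probability `don_at_departure_prob`
(default 1: don 3–10 min before departure, doff 5–30 min after return),
plus at-home wear blocks that top daily wear up towards a group target
(defaults 10.6 h experienced users, 4.5 h first-time users, SD 1.5 h,
loosely imitating published wear-time patterns — configuration, not
fixture truth).  Intended non-wear gaps are kept ≥ 70 min so they exceed
the detector's 60-min floor; intervals closer than that are merged.
Every excursion boundary carries a 180-s transition walk; other stepping is
scattered in 20–45 s snatches (2/h at home, 8/h away) that can never form a
qualifying bout, so transitions mark exactly the excursion boundaries.

The wrist renderer works at the signal level so the counts stage is
exercised, not bypassed: doffed time is a fixed gravity orientation plus
0.003 g Gaussian noise (far below the 0.068 g dead-band after filtering);
worn time adds an orientation shift, movement bursts at 2 Hz (inside the
pass-band, 0.7 g) at the start and end of each wear interval and at least
every 12 min within it, and 1.9 Hz arm-swing during stepping.  The thigh
renderer maps sleep to primary lying and bouts to stepping seconds, with
per-bout step totals conserving cadence × duration exactly
(largest-remainder allocation); remaining seconds are a sedentary/upright
mix.  Low-coverage days (optional) drop a block of epochs outright,
exercising the valid-day rule.

All randomness derives from one seed via per-participant child seeds;
identical configurations reproduce identical cohorts bit for bit.

### What the synthetic data does and does not show

It reproduces the *structure* real recordings are assumed to have: distinct
quiescent/active wrist states, excursions bounded by sustained walks,
sleep-anchored days.  It does not reproduce biomechanically realistic gait
spectra, postural transitions, classifier noise in the thigh monitor's
labels, irregular sleep, or excursions that lack a qualifying boundary walk
(car directly from a garage, for instance).  Passing recovery tests
therefore demonstrates the pipeline's correctness under its stated
assumptions, not the field accuracy of those assumptions; the
home/away rule in particular inherits the cited transition heuristic's
blind spots.  Typical synthetic step volumes are also lower than
free-living step counts, which is immaterial here because every analysis
depends on the pattern of stepping, not its volume.

## Problem sizes

The acceptance script and end-to-end tests use an 8-participant × 7-day
cohort (≈ 242 M wrist samples processed sequentially) — large enough that
every participant-day exercises sleep anchoring, multiple wear blocks and
away excursions, while a full run stays around a minute on one CPU.  Unit
tests use single synthetic days or hand-built epoch sequences.

## Known limitations

* The count chain replicates the published passband, not a specific
  device's electronics; absolute counts should not be compared across
  implementations without cross-calibration.
* Non-wear parameters are heuristics; very still wearing longer than an
  hour is indistinguishable from non-wear with a wrist-mounted sensor.
* The final monitored day usually lacks a complete evening sleep and is
  excluded from home/away summaries by design.
* The straight-line transition rule is only active when an external heading
  series is supplied; the thigh export alone cannot provide it.
* Proprietary vendor containers (.cwa, .datx) are out of scope; inputs are
  the CSV/WAV exports of the vendor toolchains.
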
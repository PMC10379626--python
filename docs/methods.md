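# Methods

This note documents the analysis pipeline, the synthetic cohort that stands
in for the unavailable human-subject recordings, and the numerical and
design choices behind both.

## Signal processing

All filtering is a second-order low-pass Butterworth applied forward and
backward (`scipy.signal.sosfiltfilt`), which doubles the magnitude response
(effective fourth-order roll-off) and cancels the phase shift exactly — a
requirement because turn boundaries and force apices are read off the
filtered trace as time points. The nominal cutoff is used as designed, with
no double-pass attenuation correction, matching common biomechanics
practice. Edges are padded reflectively (even padding) over roughly three
cutoff periods to suppress start-up transients.

Two cutoffs are used throughout, and both are pipeline parameters:

| parameter | default | role |
| --- | --- | --- |
| `segmentation_cutoff_hz` | 0.5 Hz | aggressive smoothing for event detection (turn boundaries, force apices) |
| `feature_cutoff_hz` | 6 Hz | light smoothing before any feature value is read |

Local extrema are detected with `scipy.signal.find_peaks` plus two
thresholds: a minimum separation (default 1.0 s — carving turns last longer
than a second) and a minimum prominence of 0.25 × the filtered signal's SD,
floored at 1 N for force traces so numerically flat series cannot produce
phantom detections. Plateau extrema report their first sample, a
deterministic tie-break. Neither threshold is reported by the original
protocol; both are exposed in `PipelineConfig`.

## Edge angles from boot roll rate

A single boot's roll-rate maxima (after 0.5-Hz filtering) occur when the ski
is flat between edge changes; consecutive maxima bound one full roll cycle —
the boot's downhill (outside-ski) phase followed by its uphill phase. Right
boots are negated before processing so one sign convention serves both
sides; with that convention the two boots' maxima interleave, and together
they cover every arc of the run.

Within a window the 6-Hz-filtered roll rate is integrated by the trapezoid
rule and corrected by the line through its two endpoint values, forcing the
angle to zero at both boundaries (the ski is flat there). This endpoint
anchoring — chosen over a least-squares detrend, which would not honour the
boundary semantics — removes a constant gyro bias *exactly*: a bias
integrates to a ramp, and a ramp through the endpoints is subtracted in
full. The drift-immunity test asserts agreement below 1e-6 degrees at
5 deg/s of bias. The downhill peak is the maximum over the first half of the
window (split at the temporal midpoint), the uphill peak the magnitude of
the minimum over the second half. Automated QC replaces manual inspection:
windows outside 1–10 s or angles above 80° are flagged invalid.

## Force features

Per foot, the three insole regions (heel, medial forefoot, lateral
forefoot) are summed to a total force. Analysis is restricted to the first
15 s of each run, the protocol's clean-turn segment. Coarse apices and
minima come from the 0.5-Hz-filtered total per foot; apices are then pruned
so that retained peaks strictly alternate feet (a single forward scan that
keeps the earliest detection of every same-side run), reflecting that the
load apex alternates between downhill feet during linked carving turns. The
peaked foot is the downhill foot; turn direction is its opposite.

Features are read from the 6-Hz-filtered series only:

* **Peak downhill force** — maximum of the peaked foot's total in a
  symmetric 1-s window around the coarse apex; **peak uphill force** — the
  other foot's maximum in the same window.
* **RFD and time to peak** — the interval runs from the previous coarse
  minimum of the same foot to the apex; both endpoints are refined to the
  local extremum of the 6-Hz total within ±0.25 s of the coarse index, then
  interpolated to sub-sample positions with a three-point parabola. RFD is
  the secant slope over the refined endpoints — identical to the mean of
  first differences × sample rate on the integer grid (telescoping sum), but
  free of the 10-ms sampling quantization, which is ~0.5% of a typical
  1.9-s time to peak and would otherwise dominate the method's error budget.
* **Average force** — mean of the 6-Hz total over the same interval.

Turns without a preceding minimum in the trace are dropped; windows
truncated by the trace ends are flagged. A `baseline_zero` helper
(lowest-5%-median subtraction, floored at zero) is available for raw insole
exports whose unloaded baseline drifts, but it is not applied by default:
correctly zeroed data can carry genuine load at its minima, which must not
be subtracted.

Exclusions: trials with fewer than `min_turns_per_trial` (default 5)
retained turns are dropped; a subject with at least half of their trials
dropped is excluded entirely. The subject-level rule generalises the
trial-level criterion deterministically; both knobs are in the config.

## Static pressure

Grids are time-averaged over the trial's frames, then reduced. Dorsal
metrics are whole-pad statistics over all 180 sensels; the SD is the
population SD including zeros ("across the entire surface"). Contact area
counts sensels strictly above `contact_threshold_kpa` (default 5 kPa — no
activation threshold is given by the protocol) times the sensel area
(0.875 cm² dorsal, 1.05 cm² plantar). The plantar insole's 235 active
sensels live in a 31 × 10 bounding grid with an inactive-sensel mask;
inactive sensels never enter any statistic.

The eight plantar regions are longitudinal bands by fraction of insole
length from the heel — heel 0–30%, midfoot 30–60%, metatarsals 60–85%, toes
85–100%, a common regional-masking convention — crossed with a
medial/lateral split at the column midline, mirrored by foot side. Band
membership is decided by sensel row centers. All metrics are verified
against independent sensel-by-sensel loops to 1e-9. Pressures are reported
in kPa throughout.

## Mixed-effects inference

Three model shapes, all REML fits of `statsmodels` MixedLM:

* **eq1** (on-snow turn outcomes): fixed configuration, turn-direction and
  trial-number effects; random intercept and configuration slope per
  subject (correlated). Turn direction absorbs the off-camber slope
  asymmetry, trial number the monotonic snow deterioration.
* **eq2** (subjective scores): fixed configuration, random intercept.
  Regional fit items (forefoot, midfoot, heel, cuff) are first folded to
  `|score − 5|`, so 0 is optimal and 5 is too loose *or* too tight.
* **eq3** (static pressures): fixed configuration and shell-overlap
  effects, random intercept; both BOA tension conditions pool into one BOA
  level, so the configuration contrast is evaluated *at a given overlap* —
  isolating the mechanical effect of the closure from how tightly each
  participant chose to run it.

Estimated marginal means are computed from the fixed effects at a reference
grid holding turn direction at its observed proportion and trial number /
overlap at their observed means, with random effects at zero; the
configuration contrast then equals the configuration coefficient, and the
reported effect is `100 × (EMM_BOA − EMM_Buckle) / EMM_Buckle`. The
configuration p-value is the large-sample Wald test of that coefficient
(the protocol does not state a degrees-of-freedom approximation; the Wald
choice is calibrated empirically — see below). A singular or non-converged
random-slope fit falls back to a random intercept with a logged warning;
if even the intercept model is degenerate (possible on noise-free
simulations with zero residual variance) the fixed effects are estimated by
least squares, again logged. Fits are deterministic given the data.

Type-I calibration: under a null configuration effect, 100 simulated
20-subject cohorts reject the eq2 configuration term at a rate within
5% ± 3 points — the Wald test's mild liberality at 20 groups stays inside
that band. The eq1 EMM machinery is cross-checked against an independent
R fit (lme4 + emmeans) on one balanced dataset in the test suite.

## The synthetic cohort

The generator reproduces the *study conditions*, not skiing physics. A run
is a 1-s lead-in plus eight 3-s roll cycles (16 alternating turn arcs,
~25 s; the pipeline analyses the first 15 s, giving 8–9 apices per run —
the protocol's "top five to ten turns"). Defaults encode the published
effect table: 750 N baseline peak downhill force with +30 N (4%) under
BOA; 1.86 s time to peak, −0.13 s (7%) under BOA; +10% RFD; 583 N uphill
peak, +35 N (6%); +40 N on left turns; −10 N per trial; subject intercept
SD 60 N and configuration-slope SD 15 N; 10 N force noise, 3 deg/s gyro
noise, ~1 deg/s per-run gyro bias; 45° peak edge angles with no
configuration effect. In-lab: a 30 kPa-mean instep-centred dorsal pattern
scaled by 0.88 under BOA (−12%), plantar lateral-heel peak scaled by 0.86
(−14%) and both midfoot regions by 0.90 (−10%), with shell overlap (in
scale units relative to the typical Buckle setting) adding 1 kPa per unit
to every sensel. Subjective items draw around the study's per-item means.

One deliberate deviation from the printed absolutes: the published triple
(750 N peak, 440 N/s RFD, 1.86 s time to peak) cannot coexist in a
generator that enforces the per-turn identity RFD × time-to-peak =
peak − minimum with non-negative force at the minimum (440 × 1.86 = 818 N
of rise exceeds the 750 N peak). Published group means need not satisfy a
per-turn identity; a generator must. The baseline RFD is therefore 340 N/s
(valley ≈ 118 N, a plausible residual inside-ski load) with a +34 N/s
configuration effect, preserving the 10% ratio exactly — and it is the
percent differences that the recovery analysis targets.

Force waveforms are C¹ piecewise raised-cosine curves through per-turn
keyframes (peak, valley, and an uphill-value plateau spanning the other
foot's apex window), with zero slope at every keyframe. Three geometric
refinements make the *measured* quantities insensitive to detection jitter
and filter distortion, which the noise-free self-recovery invariant
(pipeline-recovered percent differences within 0.2 points of the injected
ratios) verifies: the descent mirrors the rise around each peak so the
smoothed apex stays centred; the valley carries symmetric flanking
keyframes so zero-phase filtering cannot drag the minimum sideways; and
the uphill plateau is entered through a small ease-in step that keeps
filter ringing below the plateau value.

What the generator does **not** emulate — and what recovery tests therefore
cannot show about real data: skiing dynamics (no terrain, speed or radius
coupling; turn durations are near-constant), sensor artefacts beyond white
noise and constant gyro bias (no random-walk drift, dropouts, saturation or
Bluetooth loss), inter-subject waveform diversity (all subjects share the
keyframe shape; only levels vary), and any systematic misalignment between
insole and boot. Real recordings will also violate the strict left/right
alternation more often than the generator does.

All randomness flows from a single seed through `numpy` `SeedSequence`
spawning, keyed by subject, configuration, trial and stream, so any run,
static trial or questionnaire is individually reproducible and cohorts are
byte-identical across re-runs.

## Problem sizes

The recovery analyses use 20 subjects × 3 trials per configuration × 8
cycles per run (≈960 analysable turns) on snow and 10 subjects × 3
conditions in the lab — the study's own dimensions — and complete in
seconds; the type-I calibration uses 100 cohorts of 20 subjects. These
sizes keep every check cheap enough to run on one CPU as part of the
ordinary test suite.

## Known limitations

* The Wald p-values are mildly liberal at small subject counts; a
  Satterthwaite or Kenward–Roger approximation would be more conservative
  but is not available in statsmodels' MixedLM.
* The eq1 random-slope structure is weakly identified for outcomes with
  little between-subject slope variance (e.g. time to peak); the intercept
  fallback then engages by design.
* Sub-sample parabolic refinement assumes a locally quadratic extremum; on
  heavily saturated or clipped force plateaus it degrades to the grid
  resolution.
* The eight-region plantar scheme uses fixed band fractions rather than
  anatomical landmarks; between-subject foot-shape variation is not
  registered.
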
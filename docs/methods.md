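# Methods

`walkreach` re-implements, as a tested library, the analysis chain of a
walk-and-reach neurophysiology experiment in unrestrained macaques: task
timing and outcome classification, markerless multi-camera 3D kinematics
with outlier cleaning, wireless broadband quality control and spike
processing, and population decoding/encoding statistics with permutation
inference. Because no public recordings accompany the protocol, a
first-class synthetic-data package generates every input with recoverable
ground truth, and all validation is property-based against that ground
truth.

## Task model

A trial is a sequence of sensor/LED events on one millisecond session
clock: start-button touch (hand fixation), a 400–800 ms fixation period, a
400 ms target cue (one of 8 targets: 2 distances × 4 left-to-right
positions), a 400–2000 ms memory period, a go cue, release of a start
button inside a 600 ms window that opens 200 ms after the go cue, target
acquisition within 600 ms (near) or 1200 ms (far, walk-and-reach), and a
300 ms hold. Outcomes are assigned by the first rule violated in temporal
order: `premature` (release before the window opens, including before the
go cue), `late_release`, `reach_timeout`, `hold_break`, else `correct`.
Button release time is release − go; movement time is acquisition −
release. Near vs far timing is compared with a Welch (unequal-variance)
two-sample t-test; the protocol names only "t-test", and Welch is the safe
default under unequal spread.

The cage frame puts the start-button midpoint at the origin: x along the
target axis, y along the walk axis, z vertical. Near targets sit at
(±65, ±195) mm × 100 mm × 600 mm with ~130 mm spacing; far targets at
1000 mm walk distance with ~210 mm spacing. The optional passage for the
control analysis has a 310 mm opening.

## Synthetic data

Every generator is a pure function of its inputs and a root seed, with one
named random substream per generator so adding a generator never perturbs
another.

* **Movement durations**: near 400 ms, far 900 ms, s.d. 40 ms — plausible
  scale constants, not measured values.
* **Kinematics**: the wrist follows a minimum-jerk path
  (s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, peak speed at the temporal midpoint) from its
  start button to the trial's target between release and acquisition,
  sampled at 60 Hz. Elbow, shoulder, and headcap are affine-offset copies
  whose endpoint offsets translate the body toward far targets. Path noise
  (default 3 mm per axis) is band-limited with a 7-frame Hann kernel
  renormalized to preserve the marginal s.d.: tracking jitter and postural
  sway are not white at 60 Hz, and white noise of that amplitude would
  present inter-frame speeds that no plausible threshold separates from
  real jumps. Endpoint scatter is 5 mm. The generator does **not** model
  gait dynamics, occlusion structure, limb-length constraints, or
  autocorrelated tracking failures; passing tests therefore demonstrate
  correctness of the pipeline's rules, not robustness to every failure
  mode of real video tracking.
* **Cameras**: four ideal pinhole VGA cameras (focal 700 px) ~2.2 m from
  the cage center, calibration known by construction. Detection noise is
  Gaussian in pixels; misses receive likelihood drawn below 0.9; outliers
  are displaced 100–300 px with high likelihood. Lens distortion and
  calibration error are out of scope.
* **Spiking**: inhomogeneous Poisson with piecewise-constant rates per
  epoch, rate = baseline × epoch gain ± depth/2 by preferred side; negative
  rates clip at zero with a log entry. The standard population
  (`build_population`) places memory-period direction depth only in PMd
  and PRR units and movement-period depth in all three areas (default
  depth 8 spikes/s, baseline ~15 spikes/s, 16 units/area).
* **Broadband**: spikes insert a biphasic 1.2 ms template (amplitude in
  integer LSBs, 1 LSB ≡ 0.25 µV, fixed); independent Gaussian channel
  noise; a common signal (line-frequency sinusoid plus band-limited
  Gaussian) added identically to all channels of an array; output
  quantized to int16 at 30 ksps.
* **Wireless dropouts**: per headstage, segments start as a Bernoulli
  process tuned to the requested loss fraction with geometric lengths
  (mean 600 samples, minimum 4 — the protocol does not characterize the
  segment-length distribution; geometric is an assumption). During a
  segment every channel of the headstage repeats its last pre-segment
  value, which is exactly the receiver's sample-and-hold behavior.

## Kinematic reconstruction and cleaning

2D detections with likelihood < 0.9 are discarded (boundary kept).
Triangulation needs at least two views: a linear DLT solution refined by
Levenberg–Marquardt least squares on the stacked pixel residuals, with
per-camera RMS reprojection error attached. Cleaning order is fixed as
likelihood → triangulation → reprojection (> 50 px on any camera) →
bounding box (closed 1320 × 740 × 750 mm) → speed → interpolation.

The speed filter is iterative: compute displacement **rates** between
consecutive surviving samples (Euclidean distance divided by the frame
gap, so the mm/frame thresholds remain meaningful across gaps left by
earlier rejections), flag rates exceeding the applicable threshold (wrist
12/80 mm/frame outside/during the release→acquisition interval; other
body parts 15/40), remove the 1st, 3rd, 5th… flagged samples in temporal
order (a single bad point produces two jumps), and repeat until nothing
exceeds threshold. The iteration removes at least one point per pass, so
it terminates in at most n passes. Raw gap-crossing distance against the
per-frame threshold would cascade — one removed frame inside a fast
walk-and-reach leaves a 2-frame gap whose raw displacement exceeds the
80 mm/frame limit — hence the rate normalization.

Interior gaps are filled per coordinate by monotone shape-preserving cubic
interpolation (PCHIP), flagged `interpolated`; leading/trailing gaps stay
invalid. Trials are aligned by linear interpolation onto a common
normalized time base between release − pre and acquisition + post
(100 ms windows for behavioral analysis, 300 ms when paired with neural
data). Variability is the per-trial time-average of the Euclidean distance
to the pointwise trial mean, summarized by median and 0.75-quantile pooled
over positions within a distance. The passage analysis finds each trial's
first crossing of the plane 400 mm from the start along the walk axis by
linear interpolation and compares crossing-position distributions between
blocks with a two-sample Kolmogorov–Smirnov test.

## Broadband conditioning and spikes

Data loss: a sample (t ≥ 1) is flagged iff it lies in a maximal run of at
least 4 consecutive samples whose values, on the first 32 channels of the
headstage, repeat the previous sample. The combined mask is the union over
headstages; per-trial fractions use the fixation-onset → trial-end window,
and trials with loss ≥ 5% are dropped (strictly-smaller-than-5% kept).
This repeat-based convention is the only one under which the detected mask
equals the injected sample-and-hold mask exactly, since the pre-segment
sample itself is genuine data.

Conditioning: centered 91-sample sliding-window median subtraction
(truncated windows at the edges), then a zero-phase 2nd-order Butterworth
low-pass at 5 kHz (forward–backward, so the amplitude response is |H|²:
a 5 kHz sinusoid passes at gain 1/2; reflective padding of 3× the filter
order). Common noise: PCA across channels per array; a component is
"common" when its variance share exceeds 30% **and** its loading
uniformity min|l|/max|l| exceeds 0.5 — both configurable, and the report
of every component's share, uniformity, and removal flag is always
emitted so the criterion can be audited. The protocol does not state
which components its authors removed; this criterion is a documented
default.

Spikes are threshold crossings at k = 4 robust noise s.d.
(MAD/0.6745), negative and/or positive, extremum located within a
30-sample dead time, 12/20-sample snippets; crossings are multi-unit by
construction (no sorting). The spike-density function convolves spike
times with a unit-integral Gaussian (σ = 50 ms) evaluated on a 200 Hz
grid; its single-spike peak is 1/(0.05√(2π)) ≈ 7.9788 spikes/s and its
integral over a wide window equals the spike count.

## Population statistics

Firing rates use half-open 500 ms windows before and after each of four
alignments (cue on, go, release, acquisition; 8 windows per trial).
Responsiveness screening is a per-unit fixed-effects 3-way ANOVA —
distance (2) × position (4) × window (8) with all interactions, Type II
sums of squares for robustness to mild imbalance, α = 0.05. A unit is
task-responsive if any of the seven effects is significant and
position-responsive if the position main effect or any interaction
involving position is.

Decoding groups the two left against the two right positions, separately
per distance, on 300 ms bins at 100 ms steps. The designated test bins
are 100–400 ms after cue **offset** (the memory period begins at cue
offset and can be as short as 400 ms) and 300–0 ms before acquisition.
The decoder is a linear SVM (C = 1) with per-channel z-scoring fit on the
training folds only; folds are class-stratified, fixed once per analysis
run, and reused across every bin and every permutation surrogate (fewer
than k trials in a class reduces k with a warning). The one-tailed
permutation test permutes the trial-to-direction assignment and
recomputes the full cross-validated accuracy (500 surrogates by default).
The permutation is applied to the feature rows rather than the label
vector: both express the same relabeling null, but permuting the rows
keeps every surrogate's folds stratified exactly like the observed ones —
permuting labels alone de-stratifies the surrogate folds, biases the null
accuracy low, and measurably inflates the type-I error. p is the fraction
of the null strictly above the observed value — no +1 smoothing, so p = 0
is attainable; with a very discrete accuracy grid (tiny trial counts) the
strict convention can still be mildly anti-conservative through ties. The significance
threshold is the 95% null quantile; Bonferroni ×12 (3 areas × 2
distances × 2 periods) corrects the designated-bin tests.

The population firing-rate-modulation statistic is the mean over units of
|mean rate(left) − mean rate(right)|, with a 1000-surrogate one-tailed
permutation null permuting the shared trial labels (simultaneously
recorded units see one permutation). The passage control compares a
statistic (decoding accuracy with 10-fold CV, or modulation) between
with-passage and without-passage blocks: observed difference, surrogates
permuting block membership with block sizes preserved, two-tailed p as the
fraction of the null at least as extreme in absolute value, Bonferroni ×6.

## Problem sizes

Validation runs at desk scale: calibration loops use 100-surrogate
decoding nulls on 100-trial/6-channel problems, 200-surrogate modulation
and passage nulls, and ≥200 null simulations per test; the
pattern-recovery suite uses 50 replicates of a 48-unit population on one
session's far trials with 99 surrogates, 5 folds, and corrected α.
Production defaults stay at the protocol values (500/1000 surrogates, 20-
and 10-fold CV). The orchestration pipeline demonstrates the broadband
chain on a reduced block (64 channels, ~10 s) because a full session at
192 × 30 ksps is hundreds of gigabytes; decoding consumes generated spike
times directly.

## Known limitations

* Synthetic 2D tracks carry independent per-frame detection errors; real
  markerless tracking fails in bursts (occlusion), which would stress the
  interpolation stage more than these tests do.
* Threshold crossings are treated as multi-unit; no spike sorting.
* The ANOVA treats trials as independent replicates (fixed effects), and
  the eight time windows as a factor, mirroring the screening procedure
  rather than a repeated-measures model.
* The strictly-above permutation p-value can be anti-conservative for
  coarse discrete statistics (tiny trial counts); use larger surrogate
  and trial counts or the quantile threshold when that matters.
* Camera calibration is always supplied, never estimated.
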
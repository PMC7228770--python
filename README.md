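# walkreach

Analysis pipeline for **walk-and-reach neurophysiology in unrestrained
macaques**: behavioral timing extraction from task events, markerless
multi-camera 3D kinematics with outlier cleaning, wireless broadband
quality control and spike processing, and population decoding/encoding
statistics with permutation inference — plus a first-class synthetic-data
package that generates every input with recoverable ground truth, so the
whole chain is testable without animal recordings.

It is written for systems neuroscientists who run instructed-delay
reaching paradigms in cage environments (memory-guided reaches to targets
within and beyond immediate reach) and need a tested, reproducible
implementation of the standard analysis steps for that setting.

## What it computes

**Behavior.** Trials are classified from the raw event stream by the first
violated task rule (premature / late release, reach timeout, hold break).
Button release time RT = t_release − t_go and movement time
MT = t_acquire − t_release are summarized per target distance and compared
with a Welch t-test.

**Kinematics.** Per-camera 2D tracks (x, y, likelihood) are gated at
likelihood ≥ 0.9, triangulated from ≥ 2 calibrated pinhole views (DLT +
nonlinear least squares), and cleaned by reprojection error (> 50 px on
any camera), a closed 1320×740×750 mm cage box, and an iterative speed
rule (wrist 12/80 mm/frame outside/during movement; 15/40 otherwise) that
removes the first and every second flagged point per pass until all
inter-frame displacement rates are sub-threshold. Gaps are filled with
shape-preserving cubic interpolation. Trials are aligned onto a normalized
time base for averaging, trial-to-trial variability (median and
0.75-quantile of the time-averaged Euclidean distance to the mean
trajectory), and a passage-control spread analysis (KS test on plane
crossings).

**Neural signals.** Wireless dropouts are detected as runs of ≥ 4 samples
over which none of the first 32 channels of a headstage changes value
(sample-and-hold artifact); trials with ≥ 5% loss are excluded. Broadband
(30 ksps int16) is conditioned by a 91-sample sliding-median high-pass, a
zero-phase 2nd-order 5 kHz Butterworth low-pass, and per-array PCA
common-noise removal with an auditable component report. Multi-unit
spikes are threshold crossings at 4 robust s.d.; spike-density functions
use a unit-integral Gaussian kernel (σ = 50 ms) on a 200 Hz grid.

**Population statistics.** Firing rates in half-open 500 ms windows around
four alignments feed a per-unit 2×4×8 fixed-effects ANOVA (task- and
position-responsiveness). A linear SVM (C = 1, z-scored channels,
stratified folds fixed across time bins) decodes left vs right targets in
300 ms bins at 100 ms steps, with one-tailed permutation nulls (500
surrogates; p = fraction of null above observed), the population
firing-rate-modulation statistic mean|Δrate| with a 1000-surrogate null,
Bonferroni ×12, and two-tailed passage-control comparisons (×6).

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

`examples/05_direction_decoding.py` simulates one session (220 trials, 48
direction-tuned Poisson units across M1, PMd, PRR in which memory-period
tuning exists only in PMd/PRR) and runs the decoding analysis in the
designated memory and movement bins:

```
107 walk-and-reach trials, 48 units; corrected alpha = 0.05/12
    memory  M1: accuracy 0.50 (null 95% 0.61) corrected p 1.000
    memory PMd: accuracy 0.93 (null 95% 0.59) corrected p 0.000 *
    memory PRR: accuracy 0.92 (null 95% 0.61) corrected p 0.000 *
  movement  M1: accuracy 0.93 (null 95% 0.59) corrected p 0.000 *
  movement PMd: accuracy 0.94 (null 95% 0.61) corrected p 0.000 *
  movement PRR: accuracy 0.91 (null 95% 0.60) corrected p 0.000 *
```

Premotor and parietal populations carry target-direction information
already during the memory period — before any movement — while motor
cortex becomes informative only during the movement itself; the asterisks
mark Bonferroni-corrected significance against the permutation null.
`examples/02_behavioral_timing.py` prints the matching behavioral
summary (`near: movement time 401.5 ± 38.2 ms`,
`far: 901.8 ± 39.0 ms`, Welch p < 1e-300), and the other examples cover
simulation, kinematic cleaning, and signal QC.

A thin CLI orchestrates end-to-end runs with a reproducibility manifest
(config hash + per-stage output checksums):

```bash
walkreach run-all --seed 1 --out runs/demo
walkreach validate --trials runs/demo/simulate/trials.csv
```

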
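# Methods

This note documents the models, defaults and numerical choices behind
`myophase`, and what the synthetic tests do and do not establish about real
recordings.

## Recording model

A session is a set of uniformly sampled channels per participant and stage:
MMG and EMG at 1 kHz (volts), triaxial accelerometer at 50 Hz (m/s²).  The
protocol has three stages: `pre` (five 5-s squats, 5-s pauses), `hold` (one
wall squat to exhaustion), `post` (five more squats after recovery).  Squat
activity is described by 0-based, half-open sample intervals labelled
`entering` / `held` / `exiting`; the three phases of a repetition are
contiguous and ordered.

## Synthetic-session generator

The generator emulates the statistical structure the analysis relies on; it
is not a physiological muscle model.

**Accelerometer.**  The X axis lies along the thigh: standing reads +g,
squatting to knee flexion θ reads g·cos θ, with the complementary g·sin θ
on Y.  Posture transitions are raised-cosine ramps (default 1 s — smooth
and monotone, since no kinematic model is claimed), holds are plateaus, and
Gaussian sensor noise (default σ = 0.15 m/s², MEMS-accelerometer scale) is
added.  Ground truth records every phase interval exactly.  Flexion
defaults are the measured group angles of the emulated protocol —
64.11°/64.25° for the pre/post squats and 78.44° for the wall squat —
rather than the instructed 75°/90° targets.

**Muscle channels.**  Unit white Gaussian noise is shaped by a 2nd-order
Butterworth band-pass of configurable bandwidth centred on the channel's
spectral peak (MMG 7.5 Hz, bandwidth 2 Hz; EMG 85 Hz, bandwidth 30 Hz),
then band-limited to the channel band (2–100 / 10–495 Hz).  A 2-s pre-roll
absorbs filter transients.  Amplitude is then equalised — one smooth
local-RMS pass (0.4 s window) followed by exact per-0.5-s-block
normalisation, blocks restarting at phase boundaries — and multiplied by
the target envelope: rest RMS × per-phase gain, smoothed over 50 ms at
boundaries.  Per-phase RMS therefore equals its target to within ~3 %;
residual sub-block fluctuation is the only amplitude noise, mimicking the
small window-to-window RMS scatter of real recordings.

Rest RMS and phase gains default to values that place phase-level RMS at
the magnitudes observed for the quadriceps with this sensor pairing
(MMG ≈ 0.19–0.26 V unamplified, EMG ≈ 0.38–0.46 V hardware-amplified).

**Fatigue trends.**  Over each held phase the envelope is multiplied by
`1 + s·u` (u = normalized hold time) and the shaping filter's centre
frequency is swept as `f₀·(1 + s·u)` in 0.25-s blocks with filter state
carried across blocks, giving an analytically predictable centroid
trajectory.  The analysis reports the percent change between the first and
last 10 % of the hold, which for a linear ramp is `100·0.9s/(1+0.05s)`;
`slope_for_pct_change` inverts this so a trend can be injected directly in
the reported observable.  Defaults inject the group observables of the
emulated study: +29.35 % / +15.20 % RMS and −5.98 % / −18.07 % MPF for
MMG / EMG.  Pre/post stages are generated trend-free; an optional
`post_rms_scale` multiplies post-stage gains to create a controlled
pre/post amplitude difference (default 1.0).

**Endurance times** are truncated-normal: mean 88.5 s, SD 28.48 s,
truncated at 20 s (the truncation raises the realised mean to ≈ 89.1 s).
Per-participant generators derive from `SeedSequence([seed, participant,
stream])`, a fixed counter scheme that is stable across platforms.

## Preprocessing

Butterworth band-passes are applied zero-phase (`sosfiltfilt`) by default
so phase timing stays aligned with the IMU segmentation; this doubles the
effective order (a 5th-order design acts as a 10th-order magnitude
response).  A single-pass switch exists for causal processing.  The EMG
band's printed 500 Hz upper edge equals Nyquist at 1 kHz and is not
realisable; it is clipped to 99 % of Nyquist (495 Hz) with a logged
warning.  Accelerometer smoothing is a centered moving average, default
0.5 s (25 samples at 50 Hz) — wide enough to suppress sensor noise, narrow
enough to preserve ~1-s transitions; edges use a shrinking window so no
samples are fabricated.

## Segmentation

The gradient is the first difference of the smoothed X-axis trace scaled by
the sample rate.  The median gradient over the first 2 s (assumed standing)
is subtracted; transition intervals open where |gradient| exceeds 10 % of
its peak over the recording, extend until it falls below 5 % (hysteresis
prevents chattering at the crossing), and must last ≥ 0.2 s.  The
threshold is relative, so segmentation is invariant to accelerometer
scaling.  Each descent is paired with the next ascent; gaps ≥ 1 s become
held phases (boundary inclusive); unpaired transitions are dropped with a
logged warning.  The wall squat is isolated as the interval between the
first descent and the last ascent.  "10 % … from the stationary signal" is
interpreted as 10 % of the peak baseline-corrected gradient — a scale-free
reading of an ambiguous rule; threshold, hysteresis, baseline window and
minimum durations are all exposed in `SegmentationConfig`.

On synthetic sessions at default noise the detector recovers the
repetition count exactly in ≥ 95 % of runs with mean absolute boundary
error ≈ 120 ms; boundaries are systematically inside the smoothing-widened
transitions, so errors stay below 250 ms.

Knee flexion is the arccos of the normalised dot product between the mean
acceleration vectors of the standing baseline and the phase of interest.
Both intervals must be quasi-static (mean vector ≥ 0.5 g), and the estimate
is invariant to common rotation and positive scaling of both vectors.

## Features

RMS is computed per segment; MPF is the PSD centroid restricted to the
channel's filter band (out-of-band bins contain only leakage).  1-s windows
use a Hann periodogram; segments over 2 s use Welch with 1-s sub-windows
and 50 % overlap, which stabilises phase-level MPF.  The held hold is cut
into `floor(duration)` non-overlapping 1-s windows (trailing partial second
discarded) with normalized time = window midpoint as % of duration.
Segments under 0.25 s are flagged missing and excluded from means — never
imputed, since n is tiny.  Group averaging of exertion series linearly
interpolates each participant onto a 100-point percentage-of-duration grid
before the mean and SD envelope are formed.

## Statistics

Percent change `(post − pre)/pre × 100` is reported to 2 decimals; the
three-phase average is their arithmetic mean.  The Wilcoxon signed-rank
test pairs per-participant phase means, drops zero differences, and uses
the exact sign-assignment distribution up to n = 15 (mandatory at n = 5,
where the normal approximation is meaningless; verified against exhaustive
enumeration), the normal approximation beyond.  All tests are two-sided;
no multiple-testing correction is applied.  Trend analysis fits ordinary
least squares on the group-mean series over the normalized-time grid,
reporting Pearson r, its two-sided t-distribution P, the slope, and the
first/last-10 % percent change.  Constant series are flagged degenerate
rather than given an arbitrary r.

## Problem sizes and numerical choices

Stochastic checks use 100 random sessions for segmentation recovery and 50
seeded cohorts (5 participants each) for trend recovery; the acceptance
script averages exertion trends over 8 cohorts and draws 10 000 endurance
times.  These sizes put Monte-Carlo error well below the tolerances they
are tested against while keeping a full run in minutes on one CPU.
Filter designs use second-order sections throughout for numerical
stability.  Zero in-band power, empty segments, missing stages and
non-quasi-static flexion intervals raise or exclude with logged warnings
instead of propagating NaNs silently.

## Known limitations

* The generator reproduces band, peak, envelope and trend structure only —
  no motor-unit firing statistics, movement artifacts, electrode noise or
  impact transients.  Passing tests demonstrate the *pipeline's* recovery
  properties under realistic signal statistics, not robustness to every
  artifact of field recordings.
* The windowed-MPF observable carries a small positive centroid offset
  from band-limiting; at the narrow MMG bandwidth this dilutes a swept
  decline by roughly 10–15 % (an injected −5.98 % centre sweep is measured
  as ≈ −5 %).  The injection is left exact in centre frequency rather than
  pre-compensated.
* Group trend P-values treat the 100 interpolated grid points as
  independent observations; with ~88 underlying windows per participant
  this is mildly anticonservative under the null (≈ 95–97 % of null trends
  give P > 0.05 instead of the nominal 95 %).
* Wilcoxon "achieved confidence" style summaries are not computed; the
  test reports only the two-sided p-value.
* Loading real deposited recordings requires writing their channels into
  the package's CSV/manifest format; no downloader or format adapter is
  included.
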
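# myophase

Muscle-fatigue analytics for wearable mechanomyography (MMG), surface
electromyography (EMG) and inertial (IMU) recordings of squat exercise.

Thigh-worn sensor straps make it practical to monitor muscle activity
outside the laboratory, but raw MMG/EMG traces are only interpretable once
they are segmented into the phases of the movement that produced them.
`myophase` implements the full analysis chain for a three-stage squat
protocol — five 5-s unloaded squats, a wall squat held to exhaustion, and
five more squats after recovery — in which the accelerometer drives the
segmentation and the muscle channels carry the physiology:

1. **Preprocessing** — MMG band-passed 2–100 Hz, EMG 10–500 Hz (5th-order
   Butterworth, zero-phase), accelerometer axes smoothed with a centered
   moving average.
2. **Segmentation** — squat repetitions found where the smoothed X-axis
   accelerometer gradient exceeds 10 % of its peak relative to the
   stationary baseline; negative excursions are *entering* (descent),
   positive are *exiting* (ascent), the gap between them is *held*.
   Knee flexion is estimated from the rotation of the mean gravity vector
   against the standing baseline.
3. **Features** — per phase segment and per 1-s window of the wall-squat
   hold: RMS amplitude and mean power frequency
   `MPF = Σ fᵢPᵢ / Σ Pᵢ` from a Hann periodogram (Welch for longer
   segments).
4. **Statistics** — pre/post percent change per phase with exact Wilcoxon
   signed-rank tests on per-participant means, and during-exertion linear
   trends: Pearson *r*, two-sided *P*, slope *b* per unit normalized time,
   and the percent change between the first ("fresh") and last ("tired")
   10 % of the hold.

Because the pipeline is meant to be testable without any recordings, the
package ships a first-class synthetic-session generator: band-shaped
Gaussian noise with the spectral peaks typical of the quadriceps (MMG
~7–8 Hz, EMG ~80–90 Hz), phase-locked RMS envelopes, accelerometer traces
with exact ground-truth phase annotations, endurance times drawn from a
truncated normal (mean 88.5 s, SD 28.48 s, ≥ 20 s), and injectable linear
fatigue trends (RMS rise, MPF decline) during the hold.

## Worked example

Run the during-exertion analysis on a synthetic five-participant cohort:

```python
from myophase import PipelineConfig, run_exertion

cfg = PipelineConfig(seed=3, out_dir="demo_out", n_participants=5)
rep = run_exertion(cfg)
print({k: round(v, 1) for k, v in rep.hold_durations_s.items()})
print(f"mean knee flexion during hold: {rep.flexion_deg:.1f} deg")
for t in rep.trends:
    print(f"{t.channel} {t.metric.upper():3s}: r={t.r:+.3f}  P={t.p:.2e}  "
          f"b={t.slope:+.4g}  first/last-10% change={t.pct_change_first_last:+.2f}%")
```

prints

```
{'P01': 50.6, 'P02': 69.8, 'P03': 36.1, 'P04': 53.3, 'P05': 124.6}
mean knee flexion during hold: 78.5 deg
MMG RMS: r=+0.987  P=4.29e-80  b=+0.0006275  first/last-10% change=+29.40%
MMG MPF: r=-0.743  P=8.24e-19  b=-0.006586  first/last-10% change=-8.44%
EMG RMS: r=+0.983  P=4.28e-74  b=+0.0007722  first/last-10% change=+14.95%
EMG MPF: r=-0.992  P=2.23e-90  b=-0.1661  first/last-10% change=-16.84%
```

Each participant's wall squat lasted a different time (drawn from the
endurance distribution), so the per-second features are averaged on a
percentage-of-duration axis before the group trend is fitted.  Both RMS
trends rise significantly over the hold (muscle recruitment increasing as
fatigue sets in) while both MPF trends decline (slowing motor-unit firing),
with the injected effect sizes recovered by the regression.  `demo_out/`
receives tidy CSVs (`hold_series.csv`, `exertion_trends.csv`,
`hold_durations.csv`), a trend figure, and every file header records the
seed and config hash.

The same configuration drives the pre/post comparison
(`run_prepost`), which emits a per-phase comparison table
(raw V/Hz values, percent change and Wilcoxon *P* per contraction phase)
plus group plots, or everything at once from the shell:

```bash
myophase all --participants 5 --seed 3 --out demo_out
myophase generate --participants 5 --seed 3 --out session_dir   # CSVs + manifest
```

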
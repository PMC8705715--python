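# hrvguide

Tools for prescribing daily training intensity from morning heart rate
variability (HRV), for sport scientists, coaches and methods researchers who
want the full decision pipeline — not just the HRV math — as tested,
scriptable code.

High-intensity functional training (HIFT) mixes aerobic, weightlifting and
bodyweight work in constantly varied sessions, which makes external-load
accounting hard; internal load monitored through HRV is a practical
alternative. The procedure implemented here modulates each day's session from
the athlete's own autonomic state:

* **Daily score.** Morning RMSSD (root mean square of successive differences
  of R-R intervals, ms) is transformed to `hrv_daily = 2 ln(RMSSD)`,
  an ~1–10 scale. Raw interval series are artifact-filtered first.
* **Calibration.** A 14-day baseline gives an individual mean *m* and sample
  SD *s*; smallest-worthwhile-change windows are SWC1 = *m* ± 0.5 *s* and
  SWC2 = *m* ± 1 *s*.
* **Decision.** Each training morning the trailing 7-day rolling average
  `hrv7` is classified: inside SWC1 → train as programmed (FULL); between
  SWC1 and SWC2 → repetitions and load cut 25% (REDUCED); outside SWC2 → a
  fixed 20-minute active-recovery session (RECOVERY). The baseline is
  recalibrated at a program's mid-point.
* **Reporting.** Percent change `100(post − pre)/pre`, pooled-SD effect
  sizes `d = Δmean / √((SD₁² + SD₂²)/2)` with small/medium/large classes at
  0.2/0.5/0.8, days at high intensity (DHI), training adherence and
  HRV-recording compliance.

A two-arm trial simulator (HRV-guided vs predetermined training over an
11-week, 30-session timeline) exercises the whole pipeline end-to-end and
supports parameter-recovery and null-model checks; see `docs/methods.md` for
the model and its assumptions.

The core rule is exposed as a scikit-learn-style estimator:

```python
from hrvguide import SWCPrescriber

est = SWCPrescriber().fit(baseline_scores)   # 14 daily hrv_daily values
est.predict([8.1, 8.35, 7.2])                # e.g. ['FULL', 'REDUCED', 'RECOVERY']
```

## Worked example

Simulate a 26-per-arm trial and summarize it:

```bash
hrvguide run --seed 7 --out demo
cat demo/summary.txt
```

prints, among the full outcome table:

```
  body_fat_pct           predetermined     31.87 ±   8.04 ->    27.05 ±   8.28    -15.11%  d=+0.59 (medium)
  resting_hr_bpm         guided            73.08 ±   8.44 ->    69.45 ±   9.76     -4.96%  d=+0.40 (small)
  squat_kg               guided            81.82 ±  40.91 ->    98.07 ±  40.91    +19.86%  d=-0.40 (small)

Intervention metrics

  guided         n= 26  DHI  16.8 ±  4.8  adherence  85.4%  HRV compliance  95.6%
  predetermined  n= 26  DHI  26.4 ±  1.7  adherence  88.1%  HRV compliance  95.9%
```

Reading: the predetermined arm dropped body fat 15.1% (a medium within-group
effect, d is positive for decreases); the guided arm's resting HR fell ~5%.
The key contrast is in the intervention metrics: at similar adherence, the
guided arm trained far fewer days at full intensity (16.8 vs 26.4 of 30
scheduled) because roughly a third of its attended sessions were modulated
down — the simulator's training-stress dynamics push the rolling average
outside the SWC windows, exactly as the decision rule intends.

The same artifacts (`daily_log.csv`, `session_log.csv`, `outcomes.csv`,
`profiles.csv`, summary tables) are available from Python via
`hrvguide.io.run_pipeline`; the CLI also offers `simulate`, `calibrate`,
`decide` and `analyze` subcommands for running the pieces against your own
CSV logs (schemas in `src/hrvguide/io.py`).

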
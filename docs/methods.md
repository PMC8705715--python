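# Methods

## The prescription procedure

`hrvguide` implements daily training-intensity modulation from morning heart
rate variability (HRV). The monitored quantity is RMSSD — the root mean
square of successive differences of inter-beat (R-R) intervals, in ms — which
indexes cardiac-vagal activity. Because RMSSD is right-skewed it is
log-transformed and, following common practice in athlete-monitoring apps,
multiplied by two so the score sits on an approximately 1–10 display scale:

    hrv_daily = 2 ln(RMSSD).

The score is dimensionless even though field reports sometimes label it "ms".

**Calibration.** A 14-day baseline of one-per-morning readings gives an
individual mean m and sample SD s (n−1 denominator; conventional for
small-sample individual baselines). Two smallest-worthwhile-change windows
are set symmetrically around the mean: SWC1 = m ± 0.5 s and SWC2 = m ± 1.0 s.
A minimum of 10 of the 14 days is required. A zero-SD baseline is legal but
degenerate: both windows collapse onto the mean, the profile is flagged, and
every subsequent day classifies FULL (no z-scores are formed, so no division
by zero arises).

**Monitoring.** Decisions use the trailing 7-calendar-day rolling average of
the score (`hrv7`), not single-day values, because the rolling average is a
much less noisy indicator of sustained autonomic shift: for i.i.d. daily
noise with SD σ the rolling mean has SD σ/√7. Missing days are handled by
averaging the readings available in the window, with a minimum of 4 of 7;
below that the previous day's decision context is carried forward and
flagged. Calendar-day windows are used (not last-7-readings windows), reading
"seven-day rolling average" as calendar time.

**Decision rule.** With deviation d = hrv7 − m:

| condition            | tier     | action                                            |
|----------------------|----------|---------------------------------------------------|
| |d| ≤ 0.5 s          | FULL     | train as programmed                               |
| 0.5 s < |d| ≤ 1.0 s  | REDUCED  | repetitions and external load × 0.75              |
| |d| > 1.0 s          | RECOVERY | fixed 20-min active recovery, below 50% HRR       |

Both directions of deviation modulate, per the two-sided ± window definition
(some HRV-guided literature modulates only on decreases; the symmetric rule is
the one implemented and tested here). Boundary ties go to the milder tier;
since ties at a continuous boundary are measure-zero this only matters for
constructed inputs, and the comparison carries a ~1e-9 relative tolerance so
a score placed exactly on a window edge is not tipped over by floating-point
rounding. Repetitions after the 25% cut are rounded half-down with a floor of
one rep for any block that had at least one (conservative volume reduction);
loads are reduced continuously in kg. After the first 15-session block the
baseline and both windows are recalculated from the most recent 14 days of
readings before the second block starts (spanning late block-1 and the
mid-point week), because training itself shifts resting HRV.

The procedure is packaged as a scikit-learn-style estimator,
`SWCPrescriber(swc1=0.5, swc2=1.0, min_days=10, ddof=1)`: `fit` consumes
baseline scores and exposes `mean_`, `sd_`, `swc1_bounds_`, `swc2_bounds_`,
`degenerate_`; `predict` maps rolling averages to tiers;
`decision_function` returns signed deviations. The module-level functions
(`calibrate_baseline`, `decide`, …) wrap it.

**Days at high intensity (DHI).** A session counts toward DHI iff it was
attended and executed at full, unmodulated intensity. Attended sessions of a
predetermined (non-guided) arm always count. Reports also carry
`modulated_days` (attended REDUCED or RECOVERY sessions) so both accountings
of "modulated days" can be produced.

## Artifact filtering

Consumer photoplethysmography pipelines apply proprietary artifact
correction; this package uses a simple, fully documented ectopic-beat
heuristic instead: an interval is removed when its relative deviation from
the median of the 5-interval window centred on it exceeds a threshold
(default 0.3). The sweep is iterated to a fixed point, which makes the filter
idempotent even when adjacent artifacts mask each other in a single pass.
This is deliberately a basic filter: it handles isolated ectopic beats and
missed/double detections, not sustained arrhythmia or motion corruption.

## The trial simulator

`simulate_trial` generates a two-arm (HRV-guided vs predetermined) cohort
over an 11-week timeline: 14 baseline days, a pre-testing week, two
three-week training blocks of 15 sessions each (Monday–Friday, weekends
off), a mid-point recalibration week, and a post-testing week — 77 days and
30 scheduled sessions per participant. The guided arm runs the full
calibrate → rolling average → decide pipeline each training morning.

The HRV dynamics are an invented generative model (no individual-level
trajectories exist publicly to fit one):

    hrv_daily(t) = mu_i − s_i(t) + eps_t,   eps_t ~ N(0, daily_sd) i.i.d.

with trait mean mu_i ~ N(8.5, 1.1²) and an accumulated-stress state s_i(t)
that rises by `stress_delta_full` (default 0.15 score units) after an
attended full session, by 0.75× that after a REDUCED session, and by nothing
after RECOVERY or a missed session, decaying exponentially with half-life
`recovery_halflife_days` (default 2 days). Session attendance is
Bernoulli(0.88) and morning-reading compliance Bernoulli(0.95), independent
day to day. `daily_sd` defaults to 0.8 so the simulated day-to-day CV of the
score lands in the 9–10% band typical of daily HRV monitoring at a mean near
8.5. Setting the stress deltas to zero (`TrialConfig.null()`) gives a pure
i.i.d. null in which the daily tier probabilities have the closed form
P(FULL) = 2Φ(0.5√7) − 1 ≈ 0.814, P(RECOVERY) = 2(1 − Φ(√7)) ≈ 0.008 when
classified against windows built from the known σ. Note that inside a
simulated trial the windows are *estimated* from 14 baseline days, which
adds baseline sampling error to the deviation and noise to the threshold;
the realized FULL fraction under the null is therefore systematically below
the known-parameter closed form (~0.70 rather than 0.814), and the tests
check it against a matching estimated-baseline oracle.

What the simulator emulates: timeline structure, one-reading-per-morning
compliance gaps, attendance, the within-person stationarity of baseline HRV,
and a monotone dose–response between accumulated training stress and score
suppression. What it does not: sleep, illness, menstrual-cycle and lifestyle
covariates, non-Gaussian daily noise, measurement-protocol violations, or
any physiologically validated stress–recovery kinetics. Passing tests
therefore demonstrate the *procedure's* correctness and its behaviour under
a controlled generative model, not real-world effectiveness.

Rare edge case: with compliance 0.95 a simulated participant can finish the
baseline with fewer than 10 readings (probability ≈ 6e-6); the simulator then
calibrates on whatever is available (minimum 2) rather than aborting the
trial.

**Outcomes.** Pre/post outcome pairs are drawn per arm from a
bivariate-normal test–retest model: with pre ~ N(μ, σ²), test–retest
correlation r (default 0.9, realistic for body-composition and strength
measures over weeks), and true standardized change δ,

    post = μ + δσ + r(pre − μ) + √(1 − r²) σ z,   z ~ N(0, 1).

This keeps the post SD equal to the pre SD marginally, so the configured δ is
exactly the within-group pooled-SD effect size in expectation and is
recoverable from (mean, SD) summaries — the residual-noise model was chosen
for that identifiability. Default outcome distributions (resting HR, body
composition, VO2max, work capacity, lifts) are typical of recreationally
active adults over 11 weeks of high-intensity functional training.

## Summary statistics

Percent change is computed on group means, 100(post − pre)/pre. Effect sizes
use the pooled-SD form d = (mean₁ − mean₂)/√((SD₁² + SD₂²)/2); within-group d
is reported signed with the convention positive = decrease (and in absolute
value), because sign conventions in published tables of this kind are
inconsistent across rows. Classification: |d| ≥ 0.2 small, ≥ 0.5 medium,
≥ 0.8 large (ties upward; below 0.2 reported as "trivial"). Between-group
effect sizes on raw data use per-participant change scores; on summaries, the
two groups' (mean, SD) directly. Published cells that are not reproducible
from any summary-based formula are not asserted anywhere. Linear mixed-model
adjusted contrasts are out of scope: they require participant-level data, and
standard facilities (statsmodels `mixedlm`, R `lme4`) cover them.

## Problem sizes used in checks

The bundled checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances they assert: 60,000 independent decision days for
the null fractions (3 binomial SEs), 1,000 replicates for baseline-mean
recovery (nominal coverage 99.73% against a ≥99% bound), 1,000 participants
per arm for effect-size recovery, and 100 replicate trials of 4+4
participants for the guided-vs-predetermined DHI sign test.

## Known limitations

* The stress–response kinetics and all simulator defaults are assumptions;
  none are fit to data.
* The artifact filter is a local-median heuristic, not a validated beat
  classifier.
* The recalibration data window (last 14 days before block 2) is one
  reasonable reading of "recalculated for the second training period";
  alternatives (mid-point week only) are configurable via `window_days`.
* Whether real deployments compute the rolling average over calendar days or
  over the last 7 readings varies by app; calendar days are used here.
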
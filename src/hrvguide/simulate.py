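"""Synthetic two-arm trial generator.

Simulates an 11-week randomized trial comparing HRV-guided and predetermined
high-intensity functional training: a 14-day baseline of morning readings,
a pre-testing week, two 15-session training blocks (Monday-Friday) separated
by a mid-point week in which the guided arm's baseline and SWC windows are
recalculated, and a post-testing week. The guided arm runs the full
calibrate -> rolling average -> decide pipeline every training morning; the
predetermined arm trains as programmed.

Generative model (invented, documented here; no individual-level trajectories
exist to validate against):

* participant trait mean mu_i ~ Normal(baseline_mean_mean, baseline_mean_sd)
  on the ~1-10 score scale;
* daily score hrv_daily(t) = mu_i - s_i(t) + eps_t with eps_t i.i.d.
  Normal(0, daily_sd);
* accumulated training stress s_i(t) rises by ``stress_delta_full`` after an
  attended full-intensity session (x0.75 of it after a REDUCED session, 0
  after RECOVERY or a missed session) and decays exponentially with half-life
  ``recovery_halflife_days``;
* session attendance is Bernoulli(adherence_prob), morning-reading compliance
  Bernoulli(hrv_compliance_prob), both independent day to day.

Setting the stress deltas to zero (``TrialConfig.null``) gives a pure i.i.d.
normal null for which the daily decision probabilities have a closed form:
the 7-day mean has SD sigma/sqrt(7), so
P(FULL) = 2 Phi(0.5 sqrt 7) - 1 ~ 0.814 and
P(RECOVERY) = 2 (1 - Phi(sqrt 7)) ~ 0.008.

Pre/post outcomes are drawn from a bivariate-normal test-retest model: with
test-retest correlation r, post = pre_mean + change_std * pre_sd +
r (pre - pre_mean) + sqrt(1 - r^2) pre_sd z, so the post SD equals the pre SD
and the configured standardized change is recoverable from group summaries.
"""

from __future__ import annotations

import dataclasses
import datetime
import math

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import calibrate_baseline, recalibrate, rolling_hrv7
from .decision import FULL, RECOVERY, REDUCED, TrainingDecision, classify_dhi, decide
from .hrv import DailyReading
from .prescriber import classify_deviation

__all__ = [
    "ArmOutcome",
    "OutcomeSpec",
    "TrialConfig",
    "TrialDataset",
    "TimelineDay",
    "default_outcomes",
    "build_timeline",
    "simulate_participant",
    "simulate_trial",
    "generate_outcomes",
    "null_decision_fractions",
    "null_decision_probabilities",
]

GUIDED = "guided"
PREDETERMINED = "predetermined"


@dataclasses.dataclass(frozen=True)
class ArmOutcome:
    """Pre-test distribution and true standardized change for one arm."""

    pre_mean: float
    pre_sd: float
    post_mean: float

    @property
    def change_std(self) -> float:
        """True standardized change, (post mean - pre mean) / pre SD."""
        return (self.post_mean - self.pre_mean) / self.pre_sd


@dataclasses.dataclass(frozen=True)
class OutcomeSpec:
    name: str
    guided: ArmOutcome
    predetermined: ArmOutcome
    retest_r: float = 0.9

    def arm(self, arm: str) -> ArmOutcome:
        return self.guided if arm == GUIDED else self.predetermined


def default_outcomes() -> tuple[OutcomeSpec, ...]:
    """Pre/post outcome distributions typical of an 11-week HIFT cohort.

    (name, guided pre mean, pre SD, post mean, predetermined pre mean, pre SD,
    post mean); recreationally active adults.
    """
    rows = [
        ("resting_hr_bpm", 73.6, 9.8, 69.3, 74.6, 14.6, 72.7),
        ("hrv_daily", 8.4, 1.1, 8.6, 8.7, 1.2, 8.7),
        ("cv_of_hrv_pct", 10.1, 3.9, 9.0, 8.7, 3.3, 9.5),
        ("body_fat_pct", 31.8, 11.1, 29.2, 31.8, 8.3, 26.8),
        ("lean_mass_kg", 54.5, 13.5, 54.8, 52.6, 11.2, 54.0),
        ("fat_mass_kg", 23.9, 8.8, 23.5, 23.9, 8.8, 20.3),
        ("vo2max_ml_kg_min", 42.1, 6.8, 43.0, 44.4, 6.4, 44.2),
        ("work_capacity_reps", 131.0, 36.0, 147.0, 127.0, 24.0, 145.0),
        ("squat_kg", 90.2, 44.5, 103.0, 87.6, 33.2, 99.1),
        ("press_kg", 41.6, 18.9, 45.3, 41.5, 16.2, 45.5),
        ("deadlift_kg", 103.0, 46.0, 116.0, 107.0, 34.0, 121.0),
        ("crossfit_total_kg", 232.0, 109.0, 259.0, 237.0, 82.0, 266.0),
    ]
    return tuple(
        OutcomeSpec(name, ArmOutcome(gm, gs, gp), ArmOutcome(pm, ps, pp))
        for name, gm, gs, gp, pm, ps, pp in rows
    )


@dataclasses.dataclass
class TrialConfig:
    """Parameters of the simulated trial; defaults mirror the study design."""

    n_per_arm: int = 26
    seed: int = 0
    start_date: datetime.date = datetime.date(2021, 3, 1)  # a Monday
    # timeline
    baseline_days: int = 14
    sessions_per_block: int = 15
    n_blocks: int = 2
    train_days_per_week: int = 5
    # HRV generative model (score units on the ~1-10 scale)
    baseline_mean_mean: float = 8.5
    baseline_mean_sd: float = 1.1
    daily_sd: float = 0.8  # puts day-to-day CV near 9-10% at a mean of ~8.5
    stress_delta_full: float = 0.15
    recovery_halflife_days: float = 2.0
    # behaviour
    adherence_prob: float = 0.88
    hrv_compliance_prob: float = 0.95
    # resting heart rate model (bpm)
    rhr_mean: float = 74.0
    rhr_between_sd: float = 10.0
    rhr_within_sd: float = 3.0
    # calibration / decision knobs
    min_baseline_days: int = 10
    min_window_readings: int = 4
    rolling_window_days: int = 7
    swc1: float = 0.5
    swc2: float = 1.0
    # outcomes
    outcomes: tuple[OutcomeSpec, ...] = dataclasses.field(default_factory=default_outcomes)

    def __post_init__(self) -> None:
        if isinstance(self.start_date, str):
            self.start_date = datetime.date.fromisoformat(self.start_date)
        for name in ("baseline_mean_sd", "daily_sd", "stress_delta_full"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("adherence_prob", "hrv_compliance_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_per_arm < 1 or self.sessions_per_block < 1 or self.n_blocks < 1:
            raise ValueError("n_per_arm, sessions_per_block and n_blocks must be >= 1")
        if not 1 <= self.train_days_per_week <= 7:
            raise ValueError("train_days_per_week must lie in 1..7")

    @classmethod
    def null(cls, **kwargs) -> "TrialConfig":
        """Pure i.i.d. configuration: no training effect on the daily score."""
        kwargs.setdefault("stress_delta_full", 0.0)
        return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class TimelineDay:
    index: int
    date: datetime.date
    phase: str  # baseline | pretest | block | recalibration | posttest
    block: int | None = None  # 1-based block number during block weeks
    training: bool = False
    block_start: bool = False  # first training day of a block


def build_timeline(config: TrialConfig) -> list[TimelineDay]:
    """Day-by-day schedule: baseline, pre-test, training blocks with
    recalibration weeks between them, post-test. Training falls on the first
    ``train_days_per_week`` days of each block week until the block's session
    quota is met."""
    baseline_weeks = math.ceil(config.baseline_days / 7)
    block_weeks = math.ceil(config.sessions_per_block / config.train_days_per_week)
    weeks: list[tuple[str, int | None]] = [("baseline", None)] * baseline_weeks
    weeks.append(("pretest", None))
    for b in range(1, config.n_blocks + 1):
        weeks.extend([("block", b)] * block_weeks)
        if b < config.n_blocks:
            weeks.append(("recalibration", None))
    weeks.append(("posttest", None))

    days: list[TimelineDay] = []
    sessions_in_block: dict[int, int] = {}
    for w, (phase, block) in enumerate(weeks):
        for dow in range(7):
            idx = 7 * w + dow
            date = config.start_date + datetime.timedelta(days=idx)
            training = False
            block_start = False
            if phase == "block" and dow < config.train_days_per_week:
                count = sessions_in_block.get(block, 0)
                if count < config.sessions_per_block:
                    training = True
                    block_start = count == 0
                    sessions_in_block[block] = count + 1
            days.append(TimelineDay(idx, date, phase, block, training, block_start))
    return days


@dataclasses.dataclass
class TrialDataset:
    """Simulated trial: daily log, session log, outcomes, and ground truth."""

    daily_log: pd.DataFrame
    session_log: pd.DataFrame
    outcomes: pd.DataFrame
    profiles: pd.DataFrame
    truth: dict
    config: TrialConfig

    @property
    def n_days(self) -> int:
        return len(build_timeline(self.config))


def _stress_delta(decision: TrainingDecision | None, config: TrialConfig) -> float:
    if decision is None or decision.value == FULL:
        return config.stress_delta_full
    if decision.value == REDUCED:
        return 0.75 * config.stress_delta_full
    return 0.0


def simulate_participant(participant_id: str, arm: str, config: TrialConfig,
                         seed) -> tuple[list[DailyReading], list[dict], dict]:
    """Simulate one participant's daily readings and session log.

    Returns (readings, session rows, truth record). ``seed`` may be an int or
    a numpy SeedSequence. Bit-for-bit reproducible for a given (config, seed).
    """
    if arm not in (GUIDED, PREDETERMINED):
        raise ValueError(f"arm must be '{GUIDED}' or '{PREDETERMINED}'")
    rng = np.random.default_rng(seed)
    timeline = build_timeline(config)
    mu = rng.normal(config.baseline_mean_mean, config.baseline_mean_sd)
    rhr_base = rng.normal(config.rhr_mean, config.rhr_between_sd)
    decay = 0.5 ** (1.0 / config.recovery_halflife_days)
    baseline_end = config.start_date + datetime.timedelta(days=config.baseline_days - 1)

    readings: list[DailyReading] = []
    session_rows: list[dict] = []
    stress = 0.0
    profile = None
    last_decision: TrainingDecision | None = None
    profile_records: list[dict] = []

    for day in timeline:
        if day.index > 0:
            stress *= decay
        if rng.random() < config.hrv_compliance_prob:
            score = mu - stress + rng.normal(0.0, config.daily_sd)
            readings.append(DailyReading(
                participant_id, day.date,
                rmssd_ms=math.exp(score / 2.0),
                rhr_bpm=max(35.0, rhr_base + rng.normal(0.0, config.rhr_within_sd)),
            ))

        if arm == GUIDED and day.block_start:
            if day.block == 1:
                base = [r for r in readings if r.date <= baseline_end]
                try:
                    profile = calibrate_baseline(
                        base, window_days=config.baseline_days,
                        min_days=config.min_baseline_days,
                        swc1=config.swc1, swc2=config.swc2)
                except ValueError:
                    # rare compliance gap: calibrate on whatever is available
                    profile = calibrate_baseline(
                        base, window_days=config.baseline_days, min_days=2,
                        swc1=config.swc1, swc2=config.swc2)
            else:
                profile = recalibrate(
                    readings, as_of=day.date, window_days=config.baseline_days,
                    min_days=config.min_baseline_days, prior=profile,
                    carry_forward=True, swc1=config.swc1, swc2=config.swc2)
            rec = dataclasses.asdict(profile)
            rec.update(block=day.block, participant_id=participant_id,
                       period_start=profile.period[0], period_end=profile.period[1])
            del rec["period"]
            profile_records.append(rec)

        if day.training:
            decision: TrainingDecision | None = None
            if arm == GUIDED:
                state = rolling_hrv7(readings, day.date,
                                     window_days=config.rolling_window_days,
                                     min_readings=config.min_window_readings)
                decision = decide(state, profile, last=last_decision)
                last_decision = decision
            attended = bool(rng.random() < config.adherence_prob)
            value = decision.value if decision is not None else None
            if attended:
                stress += _stress_delta(decision, config)
            session_rows.append({
                "participant_id": participant_id,
                "arm": arm,
                "date": day.date,
                "block": day.block,
                "scheduled": True,
                "attended": attended,
                "decision": value if value is not None else "NA",
                "volume_multiplier": (1.0 if value in (None, FULL)
                                      else 0.75 if value == REDUCED else 0.0),
                "duration_min": 20.0 if value == RECOVERY else 60.0,
                "dhi": classify_dhi({"attended": attended, "decision": value}),
                "flagged": bool(decision.flagged) if decision is not None else False,
            })

    truth = {"participant_id": participant_id, "arm": arm, "mu": mu,
             "rhr_base": rhr_base, "profiles": profile_records}
    return readings, session_rows, truth


def generate_outcomes(config: TrialConfig, participants: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw pre/post outcome values for every participant and outcome.

    Bivariate-normal test-retest model per arm (see module docstring);
    with zero residual (retest_r = 1) and zero configured change, post == pre.
    """
    rows = []
    for spec in config.outcomes:
        for _, p in participants.iterrows():
            a = spec.arm(p["arm"])
            r = spec.retest_r
            pre = rng.normal(a.pre_mean, a.pre_sd)
            z = rng.normal()
            post = (a.pre_mean + a.change_std * a.pre_sd
                    + r * (pre - a.pre_mean)
                    + math.sqrt(max(0.0, 1.0 - r * r)) * a.pre_sd * z)
            rows.append({"participant_id": p["participant_id"], "arm": p["arm"],
                         "outcome": spec.name, "pre": pre, "post": post})
    return pd.DataFrame(rows)


def simulate_trial(config: TrialConfig) -> TrialDataset:
    """Simulate both arms over the full timeline, with outcomes and truth."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_per_arm + 1)
    width = max(2, len(str(config.n_per_arm)))
    participants = (
        [(f"G{i + 1:0{width}d}", GUIDED) for i in range(config.n_per_arm)]
        + [(f"P{i + 1:0{width}d}", PREDETERMINED) for i in range(config.n_per_arm)]
    )

    daily_rows: list[dict] = []
    session_rows: list[dict] = []
    truth_rows: list[dict] = []
    profile_rows: list[dict] = []
    for (pid, arm), child in zip(participants, children):
        readings, sessions, truth = simulate_participant(pid, arm, config, child)
        for r in readings:
            daily_rows.append({"participant_id": pid, "arm": arm, "date": r.date,
                               "rmssd_ms": r.rmssd_ms, "hrv_daily": r.hrv_daily,
                               "rhr_bpm": r.rhr_bpm})
        session_rows.extend(sessions)
        profile_rows.extend(truth.pop("profiles"))
        truth_rows.append(truth)
    daily_log = pd.DataFrame(daily_rows)
    session_log = pd.DataFrame(session_rows)

    participants_df = pd.DataFrame(
        [{"participant_id": pid, "arm": arm} for pid, arm in participants])
    outcomes = generate_outcomes(config, participants_df,
                                 np.random.default_rng(children[-1]))

    truth = {
        "config": _config_record(config),
        "participants": truth_rows,
    }
    profiles = pd.DataFrame(profile_rows)
    return TrialDataset(daily_log, session_log, outcomes, profiles, truth, config)


def _config_record(config: TrialConfig) -> dict:
    rec = dataclasses.asdict(config)
    rec["start_date"] = config.start_date.isoformat()
    rec["outcomes"] = [
        {"name": s.name, "retest_r": s.retest_r,
         "guided": dataclasses.asdict(s.guided),
         "predetermined": dataclasses.asdict(s.predetermined)}
        for s in config.outcomes
    ]
    return rec


def null_decision_probabilities(swc1: float = 0.5, swc2: float = 1.0,
                                window: int = 7) -> dict[str, float]:
    """Closed-form daily tier probabilities under the i.i.d. normal null.

    The rolling mean of ``window`` i.i.d. Normal(mu, sigma^2) days is
    Normal(mu, sigma^2/window), so with windows at ±swc1*sigma and
    ±swc2*sigma: P(FULL) = 2 Phi(swc1 sqrt(window)) - 1, etc.
    """
    rt = math.sqrt(window)
    p_full = 2.0 * stats.norm.cdf(swc1 * rt) - 1.0
    p_recovery = 2.0 * (1.0 - stats.norm.cdf(swc2 * rt))
    return {FULL: p_full, REDUCED: 1.0 - p_full - p_recovery, RECOVERY: p_recovery}


def null_decision_fractions(n_decisions: int, mu: float = 8.5, sigma: float = 0.8,
                            window: int = 7, swc1: float = 0.5, swc2: float = 1.0,
                            seed=0) -> dict[str, float]:
    """Monte-Carlo tier fractions under the i.i.d. normal null with known
    (mu, sigma): each decision uses an independent full window of daily
    scores, classified against windows built from the known sigma."""
    rng = np.random.default_rng(seed)
    means = rng.normal(mu, sigma, size=(n_decisions, window)).mean(axis=1)
    tiers = classify_deviation(means - mu, sigma, swc1, swc2)
    return {t: float(np.mean(tiers == t)) for t in (FULL, REDUCED, RECOVERY)}
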
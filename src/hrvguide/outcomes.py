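"""Outcome summaries: percent change, pooled-SD effect sizes, DHI, adherence.

Group-level reporting follows the conventions of small training trials:
each outcome per group is summarized as pre/post mean ± SD, the percent
change of the group mean,

    %change = 100 (post_mean - pre_mean) / pre_mean,

and a pooled-SD standardized effect size

    d = (pre_mean - post_mean) / sqrt((pre_sd^2 + post_sd^2) / 2),

reported both signed (positive = decrease from pre to post) and in absolute
value, classified as small (|d| >= 0.2), medium (>= 0.5) or large (>= 0.8).
Between-group effect sizes use the same pooled-SD denominator on the two
groups' statistics.

Intervention metrics per participant: days at high intensity (DHI; attended,
unmodulated sessions), training adherence (% of scheduled sessions attended,
with an 80% inclusion threshold) and HRV-recording compliance (% of study
days with a morning reading).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .decision import FULL, RECOVERY, REDUCED

__all__ = [
    "GroupStats",
    "OutcomeSummary",
    "percent_change",
    "cohens_d_within",
    "cohens_d_between",
    "classify_effect_size",
    "summary_from_group_stats",
    "summarize_intervention",
    "summarize_trial",
]

ES_THRESHOLDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


@dataclasses.dataclass(frozen=True)
class GroupStats:
    """Pre/post summary of one outcome in one group (outcome units)."""

    outcome: str
    group: str
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    n: int = 2

    def __post_init__(self) -> None:
        if self.pre_sd < 0 or self.post_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def percent_change(pre_mean: float, post_mean: float) -> float:
    """Signed percent change of the group mean from pre to post."""
    if pre_mean == 0:
        raise ValueError("percent change is undefined for a zero pre-test mean")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def _pooled_sd(sd_a: float, sd_b: float) -> float:
    return math.sqrt((sd_a**2 + sd_b**2) / 2.0)


def cohens_d_within(pre_mean: float, pre_sd: float, post_mean: float,
                    post_sd: float) -> float:
    """Within-group effect size (pre - post) / pooled SD.

    Positive values indicate a decrease from pre to post. Equal means give 0
    even with zero SDs; unequal means with zero pooled SD are an error.
    """
    if pre_sd < 0 or post_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if pre_mean == post_mean:
        return 0.0
    pooled = _pooled_sd(pre_sd, post_sd)
    if pooled == 0:
        raise ValueError("effect size undefined: unequal means with zero pooled SD")
    return (pre_mean - post_mean) / pooled


def cohens_d_between(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Between-group effect size |mean_a - mean_b| / pooled SD (symmetric)."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if mean_a == mean_b:
        return 0.0
    pooled = _pooled_sd(sd_a, sd_b)
    if pooled == 0:
        raise ValueError("effect size undefined: unequal means with zero pooled SD")
    return abs(mean_a - mean_b) / pooled


def classify_effect_size(d: float) -> str:
    """small/medium/large at |d| thresholds 0.2/0.5/0.8 (>= threshold ->
    that class); below 0.2 is 'trivial'."""
    mag = abs(d)
    for threshold, label in ES_THRESHOLDS:
        if mag >= threshold:
            return label
    return "trivial"


def summary_from_group_stats(stats: list[GroupStats]) -> pd.DataFrame:
    """Percent change, within-group effect size and class from group summaries."""
    rows = []
    for s in stats:
        d = cohens_d_within(s.pre_mean, s.pre_sd, s.post_mean, s.post_sd)
        rows.append({
            "outcome": s.outcome, "group": s.group, "n": s.n,
            "pre_mean": s.pre_mean, "pre_sd": s.pre_sd,
            "post_mean": s.post_mean, "post_sd": s.post_sd,
            "pct_change": percent_change(s.pre_mean, s.post_mean),
            "within_es": d, "within_es_abs": abs(d),
            "es_class": classify_effect_size(d),
        })
    return pd.DataFrame(rows)


def summarize_intervention(session_log: pd.DataFrame, daily_log: pd.DataFrame,
                           expected_days: int | None = None,
                           adherence_threshold: float = 80.0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant and per-group intervention metrics.

    Returns (per_participant, per_group). ``expected_days`` is the number of
    study days on which a morning reading was expected; when None it is taken
    as the span of dates present in ``daily_log``.
    """
    if session_log.empty or daily_log.empty:
        raise ValueError("session and daily logs must be non-empty")
    if expected_days is None:
        dates = pd.to_datetime(daily_log["date"])
        expected_days = int((dates.max() - dates.min()).days) + 1

    rows = []
    reading_counts = daily_log.groupby("participant_id")["date"].nunique()
    for (pid, arm), grp in session_log.groupby(["participant_id", "arm"], sort=True):
        scheduled = int(grp["scheduled"].sum())
        attended = int(grp["attended"].sum())
        dhi = int(grp["dhi"].sum())
        modulated = int((grp["attended"]
                         & grp["decision"].isin([REDUCED, RECOVERY])).sum())
        adherence = 100.0 * attended / scheduled
        compliance = 100.0 * int(reading_counts.get(pid, 0)) / expected_days
        rows.append({
            "participant_id": pid, "arm": arm, "scheduled": scheduled,
            "attended": attended, "dhi": dhi, "modulated_days": modulated,
            "adherence_pct": adherence, "compliance_pct": compliance,
            "included": adherence >= adherence_threshold,
        })
    per_participant = pd.DataFrame(rows)

    group_rows = []
    for arm, grp in per_participant.groupby("arm", sort=True):
        rec = {"group": arm, "n": len(grp)}
        for metric in ("dhi", "modulated_days", "adherence_pct", "compliance_pct"):
            rec[f"{metric}_mean"] = float(grp[metric].mean())
            rec[f"{metric}_sd"] = float(grp[metric].std(ddof=1)) if len(grp) > 1 else 0.0
        rec["included_n"] = int(grp["included"].sum())
        group_rows.append(rec)
    return per_participant, pd.DataFrame(group_rows)


@dataclasses.dataclass
class OutcomeSummary:
    """Group-level trial report: outcome table and intervention-metric table."""

    outcome_table: pd.DataFrame
    intervention_table: pd.DataFrame

    def to_csv(self, outcome_path, intervention_path) -> None:
        self.outcome_table.to_csv(outcome_path, index=False)
        self.intervention_table.to_csv(intervention_path, index=False)

    @classmethod
    def from_csv(cls, outcome_path, intervention_path) -> "OutcomeSummary":
        return cls(pd.read_csv(outcome_path), pd.read_csv(intervention_path))

    def to_text(self) -> str:
        lines = ["Outcome summary (mean ± SD; d = (pre - post)/pooled SD)", ""]
        for _, r in self.outcome_table.iterrows():
            lines.append(
                f"  {r['outcome']:<22s} {r['group']:<14s} "
                f"{r['pre_mean']:8.2f} ± {r['pre_sd']:6.2f} -> "
                f"{r['post_mean']:8.2f} ± {r['post_sd']:6.2f}   "
                f"{r['pct_change']:+7.2f}%  d={r['within_es']:+5.2f} ({r['es_class']})"
            )
        lines += ["", "Intervention metrics", ""]
        for _, r in self.intervention_table.iterrows():
            lines.append(
                f"  {r['group']:<14s} n={int(r['n']):3d}  "
                f"DHI {r['dhi_mean']:5.1f} ± {r['dhi_sd']:4.1f}  "
                f"adherence {r['adherence_pct_mean']:5.1f}%  "
                f"HRV compliance {r['compliance_pct_mean']:5.1f}%"
            )
        return "\n".join(lines) + "\n"


def _group_stats_from_raw(outcomes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per outcome x group summaries and between-group change effect sizes."""
    out_rows = []
    between_rows = []
    for outcome, ogrp in outcomes.groupby("outcome", sort=True):
        change_stats = {}
        for arm, grp in ogrp.groupby("arm", sort=True):
            s = GroupStats(outcome, arm,
                           float(grp["pre"].mean()), float(grp["pre"].std(ddof=1)),
                           float(grp["post"].mean()), float(grp["post"].std(ddof=1)),
                           n=len(grp))
            out_rows.append(s)
            delta = grp["post"] - grp["pre"]
            change_stats[arm] = (float(delta.mean()), float(delta.std(ddof=1)))
        if len(change_stats) == 2:
            (ma, sa), (mb, sb) = change_stats.values()
            try:
                between = cohens_d_between(ma, sa, mb, sb)
            except ValueError:
                between = float("nan")
            between_rows.append({"outcome": outcome, "between_es": between})
    return (summary_from_group_stats(out_rows),
            pd.DataFrame(between_rows))


def summarize_trial(dataset) -> OutcomeSummary:
    """Full trial report from a TrialDataset (or any object with daily_log,
    session_log, outcomes frames and n_days)."""
    missing = [name for name in ("daily_log", "session_log", "outcomes")
               if getattr(dataset, name, None) is None or getattr(dataset, name).empty]
    if missing:
        raise ValueError(f"missing tables for trial summary: {', '.join(missing)}")
    outcome_table, between = _group_stats_from_raw(dataset.outcomes)
    outcome_table = outcome_table.merge(between, on="outcome", how="left")

    expected = getattr(dataset, "n_days", None)
    _, groups = summarize_intervention(dataset.session_log, dataset.daily_log,
                                       expected_days=expected)
    if len(groups) == 2:
        a, b = groups.iloc[0], groups.iloc[1]
        try:
            dhi_es = cohens_d_between(a["dhi_mean"], a["dhi_sd"],
                                      b["dhi_mean"], b["dhi_sd"])
        except ValueError:
            dhi_es = float("nan")
        groups = groups.assign(dhi_between_es=dhi_es)
    return OutcomeSummary(outcome_table, groups)
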
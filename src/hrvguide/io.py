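"""File formats, run configuration and the end-to-end pipeline.

Conventions: comma-separated UTF-8 CSV with a header row, "." decimal
separator, ISO-8601 calendar dates (morning readings are day-indexed; no time
zones). Every writer here has a matching reader and round-trips losslessly.

Daily-readings CSV schema (one row per participant-day):
``participant_id, date, rmssd_ms | rr_intervals_ms, rhr_bpm?, hrv_daily?``.
``rr_intervals_ms`` holds a semicolon-delimited list of inter-beat intervals;
when both intervals and a precomputed RMSSD are present the intervals win and
RMSSD is recomputed (after artifact filtering).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import pathlib

import pandas as pd
import yaml

from .calibration import BaselineProfile
from .hrv import DailyReading, RRSeries, filter_rr, rmssd
from .outcomes import summarize_trial
from .simulate import TrialConfig, TrialDataset, simulate_trial

__all__ = [
    "DataError",
    "ConfigError",
    "RunConfig",
    "read_daily_csv",
    "write_daily_csv",
    "read_session_csv",
    "save_profiles",
    "load_profiles",
    "load_run_config",
    "save_run_config",
    "write_trial_dataset",
    "run_pipeline",
]


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 1)."""


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


def read_daily_csv(path) -> list[DailyReading]:
    """Parse and validate a daily-readings CSV; row-level diagnostics on error."""
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot read {path}: {exc}") from exc
    cols = set(frame.columns)
    if not {"participant_id", "date"} <= cols:
        raise DataError(f"{path}: required columns participant_id, date; got {sorted(cols)}")
    if not ({"rmssd_ms", "rr_intervals_ms"} & cols):
        raise DataError(f"{path}: need an rmssd_ms or rr_intervals_ms column")

    readings: list[DailyReading] = []
    seen: dict[tuple[str, datetime.date], int] = {}
    errors: list[str] = []
    for i, row in frame.iterrows():
        rownum = i + 2  # header is row 1
        pid = row["participant_id"]
        try:
            date = datetime.date.fromisoformat(str(row["date"]))
        except ValueError:
            errors.append(f"row {rownum}: unparseable date {row['date']!r}")
            continue
        try:
            value = _row_rmssd(row, pid, date)
            rhr = row.get("rhr_bpm")
            rhr = float(rhr) if isinstance(rhr, str) and rhr.strip() else None
            reading = DailyReading(pid, date, rmssd_ms=value, rhr_bpm=rhr)
        except ValueError as exc:
            errors.append(f"row {rownum}: {exc}")
            continue
        key = (pid, date)
        if key in seen:
            errors.append(f"row {rownum}: duplicate participant-date "
                          f"({pid}, {date}) first seen at row {seen[key]}")
            continue
        seen[key] = rownum
        readings.append(reading)
    if errors:
        raise DataError(f"{path}: " + "; ".join(errors))
    return readings


def _row_rmssd(row, pid: str, date: datetime.date) -> float:
    raw = row.get("rr_intervals_ms")
    if isinstance(raw, str) and raw.strip():
        intervals = [float(x) for x in raw.split(";") if x.strip()]
        series, _ = filter_rr(RRSeries(pid, date, tuple(intervals)))
        return rmssd(series)
    value = row.get("rmssd_ms")
    if not (isinstance(value, str) and value.strip()):
        raise ValueError("neither rmssd_ms nor rr_intervals_ms present")
    value = float(value)
    if value <= 0:
        raise ValueError(f"nonpositive rmssd_ms {value}")
    return value


def write_daily_csv(readings: list[DailyReading], path) -> None:
    pd.DataFrame([
        {"participant_id": r.participant_id, "date": r.date.isoformat(),
         "rmssd_ms": r.rmssd_ms, "hrv_daily": r.hrv_daily, "rhr_bpm": r.rhr_bpm}
        for r in readings
    ]).to_csv(path, index=False)


def read_session_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"participant_id", "arm", "date", "scheduled", "attended",
                "decision", "dhi"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing session-log columns {sorted(missing)}")
    for col in ("scheduled", "attended", "dhi"):
        frame[col] = frame[col].astype(bool)
    return frame


def _profile_dict(profile: BaselineProfile) -> dict:
    rec = dataclasses.asdict(profile)
    rec["period"] = [profile.period[0].isoformat(), profile.period[1].isoformat()]
    return rec


def save_profiles(profiles: list[BaselineProfile], path) -> None:
    """Serialize an audit trail of baseline profiles (most recent last)."""
    pathlib.Path(path).write_text(
        json.dumps([_profile_dict(p) for p in profiles], indent=2) + "\n")


def load_profiles(path) -> list[BaselineProfile]:
    records = json.loads(pathlib.Path(path).read_text())
    out = []
    for rec in records:
        rec["period"] = tuple(datetime.date.fromisoformat(d) for d in rec["period"])
        out.append(BaselineProfile(**rec))
    return out


@dataclasses.dataclass
class RunConfig:
    """Everything an end-to-end run needs: output dir plus trial parameters."""

    out_dir: str = "hrvguide_run"
    trial: TrialConfig = dataclasses.field(default_factory=TrialConfig)


def load_run_config(path) -> RunConfig:
    try:
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"out_dir", "trial"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    trial_raw = raw.get("trial", {})
    trial_fields = {f.name for f in dataclasses.fields(TrialConfig)}
    bad = set(trial_raw) - trial_fields
    if bad:
        raise ConfigError(f"{path}: unknown trial keys {sorted(bad)}")
    if "outcomes" in trial_raw:
        raise ConfigError(f"{path}: outcome specs are not configurable from YAML")
    try:
        trial = TrialConfig(**trial_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return RunConfig(out_dir=raw.get("out_dir", "hrvguide_run"), trial=trial)


def save_run_config(config: RunConfig, path) -> None:
    trial = dataclasses.asdict(config.trial)
    trial["start_date"] = config.trial.start_date.isoformat()
    del trial["outcomes"]
    pathlib.Path(path).write_text(
        yaml.safe_dump({"out_dir": config.out_dir, "trial": trial},
                       sort_keys=True))


def _frame_with_iso_dates(frame: pd.DataFrame) -> pd.DataFrame:
    if "date" in frame.columns and len(frame):
        frame = frame.assign(date=[d.isoformat() if hasattr(d, "isoformat") else d
                                   for d in frame["date"]])
    return frame


def write_trial_dataset(dataset: TrialDataset, out_dir) -> dict[str, pathlib.Path]:
    """Write daily log, session log, outcomes, profiles and truth to a directory."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "daily_log": out / "daily_log.csv",
        "session_log": out / "session_log.csv",
        "outcomes": out / "outcomes.csv",
        "profiles": out / "profiles.csv",
        "truth": out / "truth.json",
    }
    _frame_with_iso_dates(dataset.daily_log).to_csv(paths["daily_log"], index=False)
    _frame_with_iso_dates(dataset.session_log).to_csv(paths["session_log"], index=False)
    dataset.outcomes.to_csv(paths["outcomes"], index=False)
    profiles = dataset.profiles.copy()
    for col in ("period_start", "period_end"):
        if col in profiles.columns and len(profiles):
            profiles[col] = [d.isoformat() if hasattr(d, "isoformat") else d
                             for d in profiles[col]]
    profiles.to_csv(paths["profiles"], index=False)
    paths["truth"].write_text(json.dumps(dataset.truth, indent=2, default=str) + "\n")
    return paths


def run_pipeline(config: RunConfig, seed: int | None = None,
                 out_dir=None) -> dict[str, pathlib.Path]:
    """Simulate a trial, summarize it, and write all artifacts.

    Deterministic for fixed (config, seed): rerunning produces byte-identical
    files. Returns the mapping of artifact names to paths.
    """
    trial_config = config.trial
    if seed is not None:
        trial_config = dataclasses.replace(trial_config, seed=seed)
    out = pathlib.Path(out_dir if out_dir is not None else config.out_dir)
    dataset = simulate_trial(trial_config)
    paths = write_trial_dataset(dataset, out)
    summary = summarize_trial(dataset)
    paths["summary_outcomes"] = out / "summary_outcomes.csv"
    paths["summary_intervention"] = out / "summary_intervention.csv"
    summary.to_csv(paths["summary_outcomes"], paths["summary_intervention"])
    paths["summary_text"] = out / "summary.txt"
    paths["summary_text"].write_text(summary.to_text())
    return paths
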
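"""Raw-export parsing and tabular transformation.

The raw-export dialect (documented in ``docs/raw_export_dialect.md``) stores,
per participant directory: ``meta.json`` (identity, sync events, per-day
device mode, survey responses), ``heart_rate.json`` and ``steps.json``
(per-day arrays of ``{"time": "HH:MM:SS", "value": int}`` at 1-minute steps,
local clock), ``sleep.json`` (logs with ``startTime``/``endTime`` and
run-length 30-second ``levels``) and ``summaries.json`` (device-side daily
summaries).  Timestamps on disk are local; in-memory records are naive UTC
with a per-participant fixed offset.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    HR_MAX,
    HR_MIN,
    AcceptabilityResponse,
    Cohort,
    DaySummary,
    ParticipantRecord,
    SleepPeriod,
    StageRun,
)

logger = logging.getLogger("wearcomply.ingest")

_TS_FMT = "%Y-%m-%dT%H:%M:%S"

__all__ = [
    "write_raw_export",
    "write_cohort_exports",
    "parse_raw_export",
    "parse_export_dir",
    "resample_sleep_to_minutes",
    "build_day_summaries",
    "write_epoch_csv",
    "write_summary_csv",
]


# ---------------------------------------------------------------------------
# writing

def _dump(obj: object, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n")


def _fmt_local(ts: pd.Timestamp, offset: pd.Timedelta) -> str:
    return (ts + offset).strftime(_TS_FMT)


def write_raw_export(record: ParticipantRecord, out_dir: Union[str, Path]) -> Path:
    """Serialize one record to its raw-export directory; returns the directory.

    Only minutes carrying at least one channel value are written (an unworn
    minute leaves no sample).  Output bytes are deterministic for a given
    record.
    """
    offset = record.local_offset
    pdir = Path(out_dir) / record.participant_id
    pdir.mkdir(parents=True, exist_ok=True)

    epochs = record.epochs
    local_ts = epochs["timestamp"] + offset
    days = local_ts.dt.strftime("%Y-%m-%d")
    times = local_ts.dt.strftime("%H:%M:%S")

    hr_by_day: dict[str, list] = {}
    steps_by_day: dict[str, list] = {}
    hr_vals = epochs["heart_rate"].to_numpy()
    step_vals = epochs["steps"].to_numpy()
    for day, time, hr, st in zip(days, times, hr_vals, step_vals):
        if not np.isnan(hr):
            hr_by_day.setdefault(day, []).append({"time": time, "value": int(hr)})
        if not np.isnan(st):
            steps_by_day.setdefault(day, []).append({"time": time, "value": int(st)})
    _dump(hr_by_day, pdir / "heart_rate.json")
    _dump(steps_by_day, pdir / "steps.json")

    sleep_payload = []
    for period in record.sleep:
        sleep_payload.append(
            {
                "startTime": _fmt_local(period.start, offset),
                "endTime": _fmt_local(period.end, offset),
                "levels": [
                    {
                        "dateTime": _fmt_local(run.start, offset),
                        "level": run.level,
                        "seconds": run.seconds,
                    }
                    for run in period.stage_runs
                ],
            }
        )
    _dump(sleep_payload, pdir / "sleep.json")

    clip_days = sorted(
        set(
            (epochs["timestamp"] + offset).dt.strftime("%Y-%m-%d")[
                (epochs["device_mode"] == "clip").to_numpy()
            ]
        )
    )
    meta = {
        "participant_id": record.participant_id,
        "group": record.group,
        "device_profile": record.device_profile,
        "tz_offset_minutes": record.tz_offset_minutes,
        "sync_events": [_fmt_local(s, offset) for s in record.sync_events],
        "clip_mode_days": clip_days,
        "acceptability": asdict(record.acceptability) if record.acceptability else None,
    }
    _dump(meta, pdir / "meta.json")

    summaries = [
        {
            "date": s.date.isoformat(),
            "totalSteps": s.total_steps,
            "meanHeartRate": s.mean_heart_rate,
            "wornMinutes": s.worn_minutes,
            "sleepMinutes": s.sleep_minutes,
        }
        for s in (record.day_summaries or [])
    ]
    _dump(summaries, pdir / "summaries.json")
    return pdir


def write_cohort_exports(cohort: Cohort, out_dir: Union[str, Path]) -> None:
    for record in cohort.records:
        write_raw_export(record, out_dir)


# ---------------------------------------------------------------------------
# parsing

def _load(path: Path) -> object:
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"unparseable file {path}: {exc.msg} at offset {exc.pos}") from exc


def _parse_intraday(
    payload: object, path: Path, offset: pd.Timedelta
) -> tuple[pd.Series, int, int]:
    """Flatten a per-day intraday map to a UTC-indexed Series.

    Returns (series, n_dropped_malformed, n_deduplicated).  Duplicate
    timestamps keep the last entry.
    """
    stamps: list[pd.Timestamp] = []
    values: list[float] = []
    dropped = 0
    if not isinstance(payload, dict):
        raise ValueError(f"unparseable file {path}: expected an object of day arrays")
    for day, entries in payload.items():
        if not isinstance(entries, list):
            dropped += 1
            continue
        for entry in entries:
            try:
                ts = pd.Timestamp(f"{day} {entry['time']}") - offset
                value = float(entry["value"])
                if np.isnan(value) or value < 0:
                    raise ValueError
            except (KeyError, TypeError, ValueError):
                dropped += 1
                continue
            stamps.append(ts)
            values.append(value)
    series = pd.Series(values, index=pd.DatetimeIndex(stamps), dtype=float)
    series = series.sort_index(kind="stable")
    n_dup = int(series.index.duplicated(keep="last").sum())
    if n_dup:
        series = series[~series.index.duplicated(keep="last")]
    return series, dropped, n_dup


def _parse_sleep(payload: object, path: Path, offset: pd.Timedelta) -> list[SleepPeriod]:
    if not isinstance(payload, list):
        raise ValueError(f"unparseable file {path}: expected an array of sleep logs")
    periods = []
    for log in payload:
        try:
            start = pd.Timestamp(log["startTime"]) - offset
            end = pd.Timestamp(log["endTime"]) - offset
            runs = [
                StageRun(pd.Timestamp(lv["dateTime"]) - offset, lv["level"], int(lv["seconds"]))
                for lv in log["levels"]
            ]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"unparseable file {path}: malformed sleep log ({exc})") from exc
        periods.append(SleepPeriod(start, end, runs))
    return sorted(periods, key=lambda p: p.start)


def parse_raw_export(
    participant_dir: Union[str, Path], tz_offset_minutes: Optional[int] = None
) -> ParticipantRecord:
    """Parse one raw-export directory into a validated record.

    Malformed intraday entries and out-of-range channel values are dropped
    with a logged count; duplicated timestamps are deduplicated keeping the
    last occurrence; out-of-order entries are sorted.  Overlapping sleep
    periods raise.
    """
    pdir = Path(participant_dir)
    meta = _load(pdir / "meta.json")
    if tz_offset_minutes is None:
        tz_offset_minutes = int(meta.get("tz_offset_minutes", 0))
    offset = pd.Timedelta(minutes=tz_offset_minutes)

    hr, hr_dropped, hr_dup = _parse_intraday(_load(pdir / "heart_rate.json"), pdir / "heart_rate.json", offset)
    out_of_range = int(((hr < HR_MIN) | (hr > HR_MAX)).sum())
    if out_of_range:
        hr = hr[(hr >= HR_MIN) & (hr <= HR_MAX)]
    steps, st_dropped, st_dup = _parse_intraday(_load(pdir / "steps.json"), pdir / "steps.json", offset)

    dropped = hr_dropped + st_dropped + out_of_range
    dedup = hr_dup + st_dup
    if dropped or dedup:
        logger.warning(
            "%s: dropped %d malformed/out-of-range entries, deduplicated %d",
            pdir.name, dropped, dedup,
        )

    index = hr.index.union(steps.index).sort_values()
    clip_days = set(meta.get("clip_mode_days", []))
    local_days = (index + offset).strftime("%Y-%m-%d")
    epochs = pd.DataFrame(
        {
            "timestamp": index,
            "heart_rate": hr.reindex(index).to_numpy(),
            "steps": steps.reindex(index).to_numpy(),
            "device_mode": np.where(pd.Index(local_days).isin(clip_days), "clip", "wrist"),
        }
    ).reset_index(drop=True)

    sleep = _parse_sleep(_load(pdir / "sleep.json"), pdir / "sleep.json", offset)

    summaries_payload = _load(pdir / "summaries.json")
    day_summaries = [
        DaySummary(
            date=dt.date.fromisoformat(s["date"]),
            total_steps=int(s["totalSteps"]),
            mean_heart_rate=s["meanHeartRate"],
            worn_minutes=int(s["wornMinutes"]),
            sleep_minutes=int(s["sleepMinutes"]),
        )
        for s in summaries_payload
    ] or None

    acceptability = None
    if meta.get("acceptability") is not None:
        acceptability = AcceptabilityResponse(**meta["acceptability"])

    return ParticipantRecord(
        participant_id=meta["participant_id"],
        group=meta["group"],
        device_profile=meta["device_profile"],
        epochs=epochs,
        sleep=sleep,
        sync_events=[pd.Timestamp(s) - offset for s in meta.get("sync_events", [])],
        acceptability=acceptability,
        tz_offset_minutes=tz_offset_minutes,
        day_summaries=day_summaries,
    )


def parse_export_dir(export_dir: Union[str, Path]) -> Cohort:
    """Parse every participant subdirectory of ``export_dir``."""
    root = Path(export_dir)
    records = [
        parse_raw_export(p) for p in sorted(root.iterdir()) if (p / "meta.json").exists()
    ]
    return Cohort(records=records)


# ---------------------------------------------------------------------------
# transformation

def resample_sleep_to_minutes(period: SleepPeriod) -> pd.Series:
    """Per-minute asleep mask for a sleep period.

    A minute is asleep iff at least one of its two 30-second stage records is
    a non-wake stage (the reconciliation rule between 30-second sleep epochs
    and 1-minute activity epochs).
    """
    run_slots = np.array([run.seconds // 30 for run in period.stage_runs])
    nonwake = np.repeat(
        np.array([run.level != "wake" for run in period.stage_runs]), run_slots
    )
    slot_ns = period.start.value + 30_000_000_000 * np.arange(run_slots.sum(), dtype=np.int64)
    minute_ns = slot_ns // 60_000_000_000 * 60_000_000_000
    uniq, inverse = np.unique(minute_ns, return_inverse=True)
    asleep = np.zeros(len(uniq), dtype=bool)
    np.logical_or.at(asleep, inverse, nonwake)
    return pd.Series(asleep, index=pd.DatetimeIndex(uniq), name="asleep")


def _asleep_minutes_index(record: ParticipantRecord) -> pd.DatetimeIndex:
    parts = [resample_sleep_to_minutes(p) for p in record.sleep]
    if not parts:
        return pd.DatetimeIndex([])
    mask = pd.concat(parts)
    return mask.index[mask.to_numpy()].unique().sort_values()


def build_day_summaries(record: ParticipantRecord) -> list[DaySummary]:
    """One summary per local calendar date intersecting the epoch range.

    A date with zero samples yields ``worn_minutes 0`` and an absent heart
    rate mean — never interpolated values.
    """
    from .compliance import compute_wear_mask

    if record.epochs.empty:
        return []
    offset = record.local_offset
    mask = compute_wear_mask(record.epochs)
    mask_dates = pd.Series(mask.to_numpy(), index=(mask.index + offset).date)
    worn_by_date = mask_dates.groupby(level=0).sum()

    ep = record.epochs
    ep_dates = (ep["timestamp"] + offset).dt.date
    steps_by_date = ep["steps"].groupby(ep_dates).sum(min_count=1)
    hr_by_date = ep["heart_rate"].groupby(ep_dates).mean()

    asleep_idx = _asleep_minutes_index(record)
    asleep_dates = pd.Series(1, index=(asleep_idx + offset).date) if len(asleep_idx) else pd.Series(dtype=int)
    sleep_by_date = asleep_dates.groupby(level=0).sum() if len(asleep_dates) else asleep_dates

    first = record.to_local(record.stream_start).date()
    last = record.to_local(record.stream_end).date()
    summaries = []
    day = first
    while day <= last:
        hr_mean = hr_by_date.get(day, np.nan)
        summaries.append(
            DaySummary(
                date=day,
                total_steps=int(steps_by_date.get(day, 0) if not np.isnan(steps_by_date.get(day, np.nan)) else 0),
                mean_heart_rate=None if np.isnan(hr_mean) else float(hr_mean),
                worn_minutes=int(worn_by_date.get(day, 0)),
                sleep_minutes=int(sleep_by_date.get(day, 0)),
            )
        )
        day += dt.timedelta(days=1)
    return summaries


# ---------------------------------------------------------------------------
# CSV interchange

def write_epoch_csv(cohort: Cohort, path: Union[str, Path]) -> None:
    """``participant_id,timestamp,heart_rate,steps,device_mode``; empty = absent."""
    frames = []
    for rec in cohort.records:
        ep = rec.epochs
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "timestamp": ep["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "heart_rate": ep["heart_rate"].map(lambda v: "" if np.isnan(v) else str(int(v))),
                    "steps": ep["steps"].map(lambda v: "" if np.isnan(v) else str(int(v))),
                    "device_mode": ep["device_mode"],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "timestamp", "heart_rate", "steps", "device_mode"]
    )
    out.to_csv(path, index=False)


def write_summary_csv(cohort: Cohort, path: Union[str, Path]) -> None:
    rows = []
    for rec in cohort.records:
        for s in rec.day_summaries or build_day_summaries(rec):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "date": s.date.isoformat(),
                    "total_steps": s.total_steps,
                    "mean_heart_rate": "" if s.mean_heart_rate is None else s.mean_heart_rate,
                    "worn_minutes": s.worn_minutes,
                    "sleep_minutes": s.sleep_minutes,
                }
            )
    pd.DataFrame(
        rows,
        columns=["participant_id", "date", "total_steps", "mean_heart_rate", "worn_minutes", "sleep_minutes"],
    ).to_csv(path, index=False)
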
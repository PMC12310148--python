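"""Daily monitoring rules: sync lapses, noncompliance streaks, reports.

A participant is flagged when they have not synced for ``sync_lapse_days``
whole calendar days (the sync day itself is day 0) or when the trailing run
of noncompliant in-window days reaches ``noncompliance_streak_days``.  Flags
are idempotent per (participant, type, streak start): a continuing condition
never duplicates its flag, and a flag may re-raise for a new streak after the
condition clears.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .compliance import DayCompliance, ParticipantCompliance
from .types import ParticipantRecord

__all__ = [
    "MonitoringConfig",
    "MonitoringFlag",
    "detect_sync_lapse",
    "detect_noncompliance_streak",
    "scan_participant",
    "write_flags_csv",
    "render_daily_report",
]

FLAG_SYNC = "sync_lapse"
FLAG_STREAK = "noncompliance_streak"


@dataclass(frozen=True)
class MonitoringConfig:
    sync_lapse_days: int = 3
    noncompliance_streak_days: int = 2

    def __post_init__(self) -> None:
        if self.sync_lapse_days < 1 or self.noncompliance_streak_days < 1:
            raise ValueError("monitoring thresholds must be >= 1")


@dataclass(frozen=True)
class MonitoringFlag:
    participant_id: str
    flag_type: str
    raised_on: dt.date
    detail: str
    streak_start: dt.date  # idempotence anchor


def detect_sync_lapse(
    sync_events: Sequence[pd.Timestamp],
    as_of: dt.date,
    cfg: MonitoringConfig = MonitoringConfig(),
    study_start: Optional[dt.date] = None,
    participant_id: str = "",
) -> Optional[MonitoringFlag]:
    """Flag when whole days since the last sync (or study start) reach the limit."""
    if study_start is None:
        if not sync_events:
            raise ValueError("study_start required when there are no sync events")
        study_start = pd.Timestamp(sync_events[0]).date()
    if as_of < study_start:
        raise ValueError(f"as_of {as_of} precedes study start {study_start}")
    past = [pd.Timestamp(s).date() for s in sync_events if pd.Timestamp(s).date() <= as_of]
    anchor = max(past) if past else study_start
    lapse = (as_of - anchor).days
    if lapse < cfg.sync_lapse_days:
        return None
    return MonitoringFlag(
        participant_id=participant_id,
        flag_type=FLAG_SYNC,
        raised_on=anchor + dt.timedelta(days=cfg.sync_lapse_days),
        detail=f"no sync for {lapse} days (last {anchor.isoformat()})",
        streak_start=anchor,
    )


def detect_noncompliance_streak(
    day_compliances: Sequence[DayCompliance],
    as_of: dt.date,
    cfg: MonitoringConfig = MonitoringConfig(),
    participant_id: str = "",
) -> Optional[MonitoringFlag]:
    """Flag when the trailing run of noncompliant in-window days reaches the limit."""
    days = sorted(
        (d for d in day_compliances if d.in_study_window and d.date <= as_of),
        key=lambda d: d.date,
    )
    streak: list[DayCompliance] = []
    for day in days:
        if day.compliant:
            streak = []
        else:
            streak.append(day)
    if len(streak) < cfg.noncompliance_streak_days:
        return None
    trigger = streak[cfg.noncompliance_streak_days - 1].date
    return MonitoringFlag(
        participant_id=participant_id,
        flag_type=FLAG_STREAK,
        raised_on=trigger,
        detail=f"{len(streak)} consecutive noncompliant days since {streak[0].date.isoformat()}",
        streak_start=streak[0].date,
    )


def scan_participant(
    record: ParticipantRecord,
    scored: ParticipantCompliance,
    cfg: MonitoringConfig = MonitoringConfig(),
    through: Optional[dt.date] = None,
) -> list[MonitoringFlag]:
    """Day-by-day review over the whole study; one flag per streak."""
    start = record.to_local(record.stream_start).date()
    end = through or record.to_local(record.stream_end).date()
    seen: set[tuple[str, str, dt.date]] = set()
    flags: list[MonitoringFlag] = []
    sync_local = [s + record.local_offset for s in record.sync_events]
    day = start
    while day <= end:
        for flag in (
            detect_sync_lapse(sync_local, day, cfg, start, record.participant_id),
            detect_noncompliance_streak(scored.days, day, cfg, record.participant_id),
        ):
            if flag is None:
                continue
            key = (flag.participant_id, flag.flag_type, flag.streak_start)
            if key not in seen:
                seen.add(key)
                flags.append(flag)
        day += dt.timedelta(days=1)
    return flags


def write_flags_csv(flags: Iterable[MonitoringFlag], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "flag_type", "raised_on", "detail"])
        for f in sorted(flags, key=lambda f: (f.participant_id, f.raised_on, f.flag_type)):
            writer.writerow([f.participant_id, f.flag_type, f.raised_on.isoformat(), f.detail])


def render_daily_report(
    participants: Sequence[tuple[ParticipantRecord, ParticipantCompliance]],
    as_of: dt.date,
    flags: Sequence[MonitoringFlag] = (),
    generated_at: Optional[str] = None,
) -> str:
    """Deterministic plain-HTML daily report (timestamp header optional)."""
    lines = ["<html><body>", f"<h1>Daily compliance report — {as_of.isoformat()}</h1>"]
    if generated_at is not None:
        lines.append(f"<p>generated: {generated_at}</p>")
    lines.append("<table border='1'>")
    lines.append(
        "<tr><th>participant</th><th>group</th><th>last sync</th>"
        "<th>worn min (yesterday)</th><th>day compliant</th><th>night compliant</th>"
        "<th>cumulative day rate %</th><th>active flags</th></tr>"
    )
    yesterday = as_of - dt.timedelta(days=1)
    active = {f.participant_id: [] for f in flags}
    for f in flags:
        active[f.participant_id].append(f"{f.flag_type}@{f.raised_on.isoformat()}")
    for record, scored in sorted(participants, key=lambda p: p[0].participant_id):
        syncs = [s + record.local_offset for s in record.sync_events if (s + record.local_offset).date() <= as_of]
        last_sync = max(syncs).isoformat() if syncs else "never"
        day = next((d for d in scored.days if d.date == yesterday), None)
        night = next((n for n in scored.nights if n.night_date == yesterday), None)
        in_days = [d for d in scored.days if d.in_study_window and d.date <= as_of]
        rate = (
            f"{100.0 * sum(d.compliant for d in in_days) / len(in_days):.2f}" if in_days else "-"
        )
        lines.append(
            "<tr>"
            f"<td>{record.participant_id}</td><td>{record.group}</td><td>{last_sync}</td>"
            f"<td>{day.awake_worn_minutes if day else '-'}</td>"
            f"<td>{'yes' if day and day.compliant else 'no' if day else '-'}</td>"
            f"<td>{'yes' if night and night.compliant else 'no' if night else '-'}</td>"
            f"<td>{rate}</td>"
            f"<td>{'; '.join(active.get(record.participant_id, [])) or 'none'}</td>"
            "</tr>"
        )
    lines.append("</table>")
    lines.append(f"<p>{sum(len(v) for v in active.values())} flags</p>")
    lines.append("</body></html>")
    return "\n".join(lines) + "\n"
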
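"""Core domain types shared across the pipeline.

Epoch streams are held as pandas DataFrames with one row per minute sample
(columns ``timestamp``, ``heart_rate``, ``steps``, ``device_mode``); absent
channel values are NaN.  A worn sedentary minute records ``steps == 0`` while
an unworn minute records no sample at all — downstream code must preserve the
distinction between absent and zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("acute-orthopedic", "acute-cardiac", "chronic-IIPT")
ACUTE_GROUPS = ("acute-orthopedic", "acute-cardiac")
CHRONIC_GROUP = "chronic-IIPT"

DEVICE_PROFILES = ("charge3", "inspire2")
DEVICE_MODES = ("wrist", "clip")
SLEEP_STAGES = ("wake", "light", "deep", "rem")

EPOCH_COLUMNS = ("timestamp", "heart_rate", "steps", "device_mode")

HR_MIN, HR_MAX = 25, 250


def validate_group(group: str) -> str:
    if group not in GROUPS:
        raise ValueError(f"unknown group label: {group!r} (expected one of {GROUPS})")
    return group


@dataclass(frozen=True)
class StageRun:
    """A run of identical 30-second sleep-stage records."""

    start: pd.Timestamp
    level: str
    seconds: int

    def __post_init__(self) -> None:
        if self.level not in SLEEP_STAGES:
            raise ValueError(f"unknown sleep stage {self.level!r}")
        if self.seconds <= 0 or self.seconds % 30 != 0:
            raise ValueError("stage run length must be a positive multiple of 30 s")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.seconds)


@dataclass
class SleepPeriod:
    """A logged sleep interval whose 30-second stage runs tile [start, end).

    The period is attributed to the night labeled by the date on which it
    ends (wake-up date), so a period crossing midnight belongs to exactly one
    night.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    stage_runs: Sequence[StageRun]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("sleep period end must be after start")
        cursor = self.start
        for run in self.stage_runs:
            if run.start != cursor:
                raise ValueError("stage runs must tile the sleep period exactly")
            cursor = run.end
        if cursor != self.end:
            raise ValueError("stage runs must tile the sleep period exactly")

    @property
    def night_date(self) -> dt.date:
        return self.end.date()

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start) / pd.Timedelta(minutes=1)


@dataclass
class AcceptabilityResponse:
    """Survey items on 0-10 scales plus a free-text adverse-reaction flag."""

    comfort: float
    burden: float
    sleep_disturbance: Optional[float] = None
    adverse_reaction: bool = False
    adverse_text: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("comfort", "burden", "sleep_disturbance"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 10.0):
                raise ValueError(f"{name} must lie in [0, 10], got {value}")


@dataclass(frozen=True)
class DaySummary:
    date: dt.date
    total_steps: int
    mean_heart_rate: Optional[float]
    worn_minutes: int
    sleep_minutes: int

    def __post_init__(self) -> None:
        if not (0 <= self.worn_minutes <= 1440):
            raise ValueError("worn_minutes must lie in [0, 1440]")
        if self.sleep_minutes > 1440:
            raise ValueError("sleep_minutes must be <= 1440")


def empty_epochs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": pd.Series(dtype="datetime64[ns]"),
            "heart_rate": pd.Series(dtype=float),
            "steps": pd.Series(dtype=float),
            "device_mode": pd.Series(dtype=object),
        }
    )


@dataclass
class ParticipantRecord:
    """One participant's validated device data.

    ``epochs`` timestamps are stored as naive UTC; calendar-day computations
    apply ``tz_offset_minutes`` first.  ``truth_worn`` is the simulator's
    ground-truth per-minute worn annotation (never serialized to raw
    exports); ``day_summaries`` are device-side daily summaries that survive
    on-device storage truncation.
    """

    participant_id: str
    group: str
    device_profile: str
    epochs: pd.DataFrame
    sleep: list[SleepPeriod] = field(default_factory=list)
    sync_events: list[pd.Timestamp] = field(default_factory=list)
    acceptability: Optional[AcceptabilityResponse] = None
    tz_offset_minutes: int = 0
    day_summaries: Optional[list[DaySummary]] = None
    truth_worn: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        validate_group(self.group)
        if self.device_profile not in DEVICE_PROFILES:
            raise ValueError(f"unknown device profile {self.device_profile!r}")
        ts = self.epochs["timestamp"]
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError("epoch timestamps must be sorted ascending")
        if len(ts) and ts.duplicated().any():
            raise ValueError("epoch timestamps must be strictly increasing")
        hr = self.epochs["heart_rate"]
        bad_hr = hr.notna() & ((hr < HR_MIN) | (hr > HR_MAX))
        if bad_hr.any():
            raise ValueError("heart_rate values must lie in [25, 250]")
        steps = self.epochs["steps"]
        if (steps.notna() & (steps < 0)).any():
            raise ValueError("step counts must be non-negative")
        periods = sorted(self.sleep, key=lambda p: p.start)
        for a, b in zip(periods, periods[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping sleep periods: {a.start}..{a.end} and {b.start}..{b.end}"
                )
        if any(
            b < a for a, b in zip(self.sync_events, self.sync_events[1:])
        ):
            raise ValueError("sync_events must be sorted ascending")

    # -- convenience -------------------------------------------------------

    @property
    def local_offset(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.tz_offset_minutes)

    def to_local(self, ts: pd.Timestamp) -> pd.Timestamp:
        return ts + self.local_offset

    @property
    def stream_start(self) -> pd.Timestamp:
        if self.epochs.empty:
            raise ValueError("record has no epochs")
        return self.epochs["timestamp"].iloc[0]

    @property
    def stream_end(self) -> pd.Timestamp:
        if self.epochs.empty:
            raise ValueError("record has no epochs")
        return self.epochs["timestamp"].iloc[-1]

    def copy(self) -> "ParticipantRecord":
        return replace(
            self,
            epochs=self.epochs.copy(),
            sleep=list(self.sleep),
            sync_events=list(self.sync_events),
            day_summaries=None if self.day_summaries is None else list(self.day_summaries),
            truth_worn=None if self.truth_worn is None else self.truth_worn.copy(),
        )

    def normalized(self) -> "ParticipantRecord":
        """Drop grid rows carrying no data at all (canonical raw-export view)."""
        keep = self.epochs["heart_rate"].notna() | self.epochs["steps"].notna()
        out = self.copy()
        out.epochs = self.epochs.loc[keep].reset_index(drop=True)
        return out


@dataclass
class Cohort:
    records: list[ParticipantRecord]

    def by_group(self, group: str) -> list[ParticipantRecord]:
        validate_group(group)
        return [r for r in self.records if r.group == group]

    def __len__(self) -> int:
        return len(self.records)


def records_equal(a: ParticipantRecord, b: ParticipantRecord) -> bool:
    """Field-by-field equality of the serializable surface of two records."""
    if (
        a.participant_id != b.participant_id
        or a.group != b.group
        or a.device_profile != b.device_profile
        or a.tz_offset_minutes != b.tz_offset_minutes
        or list(a.sync_events) != list(b.sync_events)
        or a.acceptability != b.acceptability
    ):
        return False
    ea, eb = a.epochs.reset_index(drop=True), b.epochs.reset_index(drop=True)
    if len(ea) != len(eb):
        return False
    if not (ea["timestamp"] == eb["timestamp"]).all():
        return False
    for col in ("heart_rate", "steps"):
        va, vb = ea[col].to_numpy(float), eb[col].to_numpy(float)
        if not np.array_equal(va, vb, equal_nan=True):
            return False
    if not (ea["device_mode"] == eb["device_mode"]).all():
        return False
    if len(a.sleep) != len(b.sleep):
        return False
    for pa, pb in zip(a.sleep, b.sleep):
        if (pa.start, pa.end, list(pa.stage_runs)) != (pb.start, pb.end, list(pb.stage_runs)):
            return False
    return (a.day_summaries or []) == (b.day_summaries or [])
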
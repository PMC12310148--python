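"""Wear inference, study-window trimming and day/night compliance scoring.

A minute counts as worn iff it carries a heart-rate sample or a step sample
with value > 0 (a recorded zero alone is not wear evidence — devices register
zero steps off-wrist); grid minutes with no sample at all are not worn.  A
day is compliant when worn minutes outside sleep periods reach the 600-minute
threshold; a night is compliant when the longest run of consecutive worn
minutes inside its logged sleep period reaches 180 minutes.  The first and
last partial calendar days and the first night are trimmed from the
denominators.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import pct
from .types import ParticipantRecord, SleepPeriod, validate_group

logger = logging.getLogger("wearcomply.compliance")

__all__ = [
    "ComplianceConfig",
    "DayCompliance",
    "NightCompliance",
    "ComplianceSummary",
    "ParticipantCompliance",
    "GroupComplianceStats",
    "GroupTotals",
    "compute_wear_mask",
    "trim_study_window",
    "score_day",
    "score_night",
    "score_participant",
    "summarize_participant",
    "aggregate_group",
    "combine_totals",
    "longest_true_run",
]


@dataclass(frozen=True)
class ComplianceConfig:
    day_threshold_min: int = 600
    night_threshold_min: int = 180
    trim_partial_edge_days: bool = True
    trim_first_night: bool = True

    def __post_init__(self) -> None:
        for t in (self.day_threshold_min, self.night_threshold_min):
            if not 0 < t <= 1440:
                raise ValueError("thresholds must lie in (0, 1440]")


@dataclass(frozen=True)
class DayCompliance:
    date: dt.date
    awake_worn_minutes: int
    compliant: bool
    in_study_window: bool


@dataclass(frozen=True)
class NightCompliance:
    night_date: dt.date
    longest_worn_run_minutes: int
    compliant: bool
    in_study_window: bool


@dataclass(frozen=True)
class ComplianceSummary:
    participant_id: str
    group: str
    compliant_days: int
    study_days: int
    compliant_nights: int
    study_nights: int
    day_rate_pct: float
    night_rate_pct: Optional[float]


@dataclass
class ParticipantCompliance:
    summary: ComplianceSummary
    days: list[DayCompliance]
    nights: list[NightCompliance]


@dataclass(frozen=True)
class StudyWindow:
    day_in_window: dict[dt.date, bool]
    night_in_window: dict[dt.date, bool]

    @property
    def study_days(self) -> list[dt.date]:
        return [d for d, ok in self.day_in_window.items() if ok]

    @property
    def study_nights(self) -> list[dt.date]:
        return [d for d, ok in self.night_in_window.items() if ok]


# ---------------------------------------------------------------------------
# wear inference

def compute_wear_mask(epochs: pd.DataFrame) -> pd.Series:
    """Per-minute worn mask over the full minute grid spanned by ``epochs``.

    worn(minute) <=> heart_rate present OR steps present with value > 0.
    Grid minutes between the first and last sample that carry no sample at
    all are not worn.
    """
    if epochs.empty:
        return pd.Series(dtype=bool)
    ts = epochs["timestamp"]
    grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="min")
    worn_rows = epochs["heart_rate"].notna() | (epochs["steps"].notna() & (epochs["steps"] > 0))
    worn = pd.Series(False, index=grid, name="worn")
    worn.loc[ts[worn_rows.to_numpy()]] = True
    return worn


def longest_true_run(values: np.ndarray) -> int:
    """Length of the longest run of consecutive True values."""
    arr = np.asarray(values, dtype=bool)
    if arr.size == 0 or not arr.any():
        return 0
    padded = np.concatenate(([0], arr.astype(np.int8), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


# ---------------------------------------------------------------------------
# trimming

def trim_study_window(record: ParticipantRecord, cfg: ComplianceConfig) -> StudyWindow:
    """Flag calendar days and nights as in/out of the analysis window.

    The first/last day is "partial" unless its epoch coverage spans from the
    first to the last minute of the date; the first logged night is excluded
    when ``trim_first_night``.
    """
    if record.epochs.empty:
        raise ValueError("record has no epoch data")
    offset = record.local_offset
    first_ts = record.stream_start + offset
    last_ts = record.stream_end + offset
    first_day, last_day = first_ts.date(), last_ts.date()

    day_in_window: dict[dt.date, bool] = {}
    day = first_day
    while day <= last_day:
        ok = True
        if cfg.trim_partial_edge_days:
            if day == first_day and first_ts > pd.Timestamp(day):
                ok = False
            if day == last_day and last_ts < pd.Timestamp(day) + pd.Timedelta(hours=23, minutes=59):
                ok = False
        day_in_window[day] = ok
        day += dt.timedelta(days=1)

    nights = sorted({(p.end + offset).date() for p in record.sleep})
    night_in_window = {d: True for d in nights}
    if cfg.trim_first_night and nights:
        night_in_window[nights[0]] = False

    if not any(day_in_window.values()):
        logger.warning("%s: no study days after trimming", record.participant_id)
    return StudyWindow(day_in_window, night_in_window)


# ---------------------------------------------------------------------------
# scoring

def asleep_mask(sleep_periods: Sequence[SleepPeriod], grid: pd.DatetimeIndex) -> np.ndarray:
    """Boolean array over ``grid`` marking minutes covered by any sleep period."""
    covered = np.zeros(len(grid), dtype=bool)
    for p in sleep_periods:
        i0 = int(np.searchsorted(grid, p.start.ceil("min"), side="left"))
        i1 = int(np.searchsorted(grid, p.end, side="left"))
        covered[i0:i1] = True
    return covered


def score_day(
    mask: pd.Series,
    sleep_periods: Sequence[SleepPeriod],
    date: dt.date,
    cfg: ComplianceConfig,
    tz_offset_minutes: int = 0,
    in_study_window: bool = True,
    _asleep: Optional[np.ndarray] = None,
) -> DayCompliance:
    """Worn minutes of the local calendar date outside any sleep period.

    Sleep periods overlapping the date are subtracted minute-wise even when
    they are attributed to a different night.
    """
    offset = pd.Timedelta(minutes=tz_offset_minutes)
    asleep = asleep_mask(sleep_periods, mask.index) if _asleep is None else _asleep
    day_start = pd.Timestamp(date) - offset  # grid time of local midnight
    i0 = int(np.searchsorted(mask.index, day_start, side="left"))
    i1 = int(np.searchsorted(mask.index, day_start + pd.Timedelta(days=1), side="left"))
    awake_worn = int((mask.to_numpy()[i0:i1] & ~asleep[i0:i1]).sum())
    return DayCompliance(
        date=date,
        awake_worn_minutes=awake_worn,
        compliant=awake_worn >= cfg.day_threshold_min,
        in_study_window=in_study_window,
    )


def score_night(
    mask: pd.Series,
    period: SleepPeriod,
    cfg: ComplianceConfig,
    tz_offset_minutes: int = 0,
    in_study_window: bool = True,
) -> NightCompliance:
    """Longest run of consecutive worn minutes within [start, end)."""
    minutes = pd.date_range(period.start.ceil("min"), period.end, freq="min", inclusive="left")
    worn = mask.reindex(minutes, fill_value=False).to_numpy(dtype=bool)
    run = longest_true_run(worn)
    return NightCompliance(
        night_date=(period.end + pd.Timedelta(minutes=tz_offset_minutes)).date(),
        longest_worn_run_minutes=run,
        compliant=run >= cfg.night_threshold_min,
        in_study_window=in_study_window,
    )


def score_participant(
    record: ParticipantRecord, cfg: ComplianceConfig = ComplianceConfig()
) -> Optional[ParticipantCompliance]:
    """Score every day and night and summarize; None when no study days remain."""
    window = trim_study_window(record, cfg)
    if not window.study_days:
        logger.warning("%s excluded: no study days", record.participant_id)
        return None
    mask = compute_wear_mask(record.epochs)
    asleep = asleep_mask(record.sleep, mask.index)

    days = [
        score_day(mask, record.sleep, date, cfg, record.tz_offset_minutes, in_window, _asleep=asleep)
        for date, in_window in window.day_in_window.items()
    ]
    nights = []
    for period in sorted(record.sleep, key=lambda p: p.start):
        night_date = (period.end + record.local_offset).date()
        nights.append(
            score_night(
                mask, period, cfg, record.tz_offset_minutes,
                in_study_window=window.night_in_window.get(night_date, False),
            )
        )

    in_days = [d for d in days if d.in_study_window]
    in_nights = [n for n in nights if n.in_study_window]
    study_days = len(in_days)
    study_nights = len(in_nights)
    compliant_days = sum(d.compliant for d in in_days)
    compliant_nights = sum(n.compliant for n in in_nights)
    summary = ComplianceSummary(
        participant_id=record.participant_id,
        group=record.group,
        compliant_days=compliant_days,
        study_days=study_days,
        compliant_nights=compliant_nights,
        study_nights=study_nights,
        day_rate_pct=pct(compliant_days, study_days),
        night_rate_pct=pct(compliant_nights, study_nights) if study_nights else None,
    )
    return ParticipantCompliance(summary=summary, days=days, nights=nights)


def summarize_participant(
    record: ParticipantRecord, cfg: ComplianceConfig = ComplianceConfig()
) -> Optional[ComplianceSummary]:
    scored = score_participant(record, cfg)
    return None if scored is None else scored.summary


# ---------------------------------------------------------------------------
# group aggregation

@dataclass(frozen=True)
class GroupTotals:
    compliant_days: int
    study_days: int
    compliant_nights: int
    study_nights: int


@dataclass
class GroupComplianceStats:
    """Table-style group aggregates: totals plus per-participant medians/ranges."""

    group: str
    n: int
    totals: GroupTotals
    median_compliant_days: float = 0.0
    range_compliant_days: tuple[float, float] = (0.0, 0.0)
    median_study_days: float = 0.0
    range_study_days: tuple[float, float] = (0.0, 0.0)
    median_day_rate: float = 0.0
    range_day_rate: tuple[float, float] = (0.0, 0.0)
    n_night: int = 0
    median_compliant_nights: Optional[float] = None
    range_compliant_nights: Optional[tuple[float, float]] = None
    median_study_nights: Optional[float] = None
    range_study_nights: Optional[tuple[float, float]] = None
    median_night_rate: Optional[float] = None
    range_night_rate: Optional[tuple[float, float]] = None
    day_rates: list[float] = field(default_factory=list)
    night_rates: list[float] = field(default_factory=list)


def _med_range(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    return float(median(values)), (float(min(values)), float(max(values)))


def aggregate_group(
    summaries: Iterable[ComplianceSummary],
    group: Optional[str] = None,
    label: Optional[str] = None,
) -> GroupComplianceStats:
    """Totals (sums over participants) and midpoint medians/ranges for a group.

    ``group`` filters by a single label; pass ``group=None`` with an explicit
    ``label`` to aggregate a pre-filtered set (e.g. the combined acute group).
    """
    if group is not None:
        validate_group(group)
        rows = [s for s in summaries if s.group == group]
    else:
        rows = list(summaries)
    if not rows:
        raise ValueError(f"no summaries for group {group or label!r}")

    totals = GroupTotals(
        compliant_days=sum(s.compliant_days for s in rows),
        study_days=sum(s.study_days for s in rows),
        compliant_nights=sum(s.compliant_nights for s in rows),
        study_nights=sum(s.study_nights for s in rows),
    )
    stats = GroupComplianceStats(group=group or label or "combined", n=len(rows), totals=totals)
    stats.median_compliant_days, stats.range_compliant_days = _med_range([s.compliant_days for s in rows])
    stats.median_study_days, stats.range_study_days = _med_range([s.study_days for s in rows])
    stats.day_rates = [s.day_rate_pct for s in rows]
    stats.median_day_rate, stats.range_day_rate = _med_range(stats.day_rates)

    night_rows = [s for s in rows if s.study_nights > 0]
    stats.n_night = len(night_rows)
    if night_rows:
        stats.median_compliant_nights, stats.range_compliant_nights = _med_range(
            [s.compliant_nights for s in night_rows]
        )
        stats.median_study_nights, stats.range_study_nights = _med_range(
            [s.study_nights for s in night_rows]
        )
        stats.night_rates = [s.night_rate_pct for s in night_rows]
        stats.median_night_rate, stats.range_night_rate = _med_range(stats.night_rates)
    return stats


def combine_totals(stats: Iterable[GroupComplianceStats]) -> GroupTotals:
    """Sum group totals across subsamples (e.g. orthopedic + cardiac -> acute)."""
    stats = list(stats)
    if not stats:
        raise ValueError("no group stats to combine")
    return GroupTotals(
        compliant_days=sum(s.totals.compliant_days for s in stats),
        study_days=sum(s.totals.study_days for s in stats),
        compliant_nights=sum(s.totals.compliant_nights for s in stats),
        study_nights=sum(s.totals.study_nights for s in stats),
    )
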
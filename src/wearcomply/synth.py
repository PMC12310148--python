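"""Synthetic minute-epoch wearable streams for a three-group pain cohort.

The simulator produces participant records with the statistical structure the
downstream analysis assumes: per-minute heart-rate/step samples realized from
group-specific wear propensities, nightly sleep logs with 30-second stage
runs, periodic sync events, charging gaps, clip-mode sensor dropout and
on-device storage truncation.  Every record retains its true per-minute worn
annotation so wear inference can be scored against ground truth.

Wear/non-wear is generated as alternating bouts with geometric lengths by
default (making the continuous-night rule nontrivial); an i.i.d.-per-minute
model is available via ``SimConfig.wear_model = "iid"``.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    ACUTE_GROUPS,
    CHRONIC_GROUP,
    GROUPS,
    AcceptabilityResponse,
    Cohort,
    ParticipantRecord,
    SleepPeriod,
    StageRun,
    validate_group,
)

__all__ = [
    "AcceptabilityProfile",
    "SimConfig",
    "DEFAULT_PROFILES",
    "generate_participant",
    "generate_cohort",
    "inject_clip_mode",
    "apply_storage_truncation",
    "write_ground_truth",
]

_BASE_DATE = dt.date(2024, 3, 4)
_GROUP_TAGS = {"acute-orthopedic": "ao", "acute-cardiac": "ac", "chronic-IIPT": "ci"}
_GROUP_DEVICES = {
    "acute-orthopedic": "inspire2",
    "acute-cardiac": "charge3",
    "chronic-IIPT": "inspire2",
}


@dataclass(frozen=True)
class AcceptabilityProfile:
    """Generating distribution of the 0-10 survey items for one group."""

    comfort_mean: float
    comfort_sd: float
    burden_mean: float
    burden_sd: float
    sleep_disturbance_mean: Optional[float] = None
    sleep_disturbance_sd: Optional[float] = None
    adverse_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adverse_prob <= 1.0:
            raise ValueError("adverse_prob must lie in [0, 1]")
        for sd in (self.comfort_sd, self.burden_sd, self.sleep_disturbance_sd):
            if sd is not None and sd < 0:
                raise ValueError("profile sds must be non-negative")


# Group-level generating parameters for the survey items; the chronic group
# additionally receives the sleep-disturbance item.
DEFAULT_PROFILES: dict[str, AcceptabilityProfile] = {
    "acute-orthopedic": AcceptabilityProfile(8.80, 1.14, 0.30, 0.48, adverse_prob=3 / 31),
    "acute-cardiac": AcceptabilityProfile(8.48, 1.60, 0.86, 1.35, adverse_prob=3 / 31),
    "chronic-IIPT": AcceptabilityProfile(8.27, 1.69, 1.15, 1.38, 0.69, 1.12, adverse_prob=6 / 26),
}

_PerGroup = Union[float, int, Mapping[str, float]]


def _per_group(value: _PerGroup, groups: Iterable[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {g: float(value[g]) for g in groups}
    else:
        out = {g: float(value) for g in groups}
    return out


@dataclass
class SimConfig:
    """Cohort-simulation parameters.

    Per-group fields (``n_per_group``, ``study_days``, ``wear_prob_day``,
    ``wear_prob_night``) accept either a scalar applied to every group or a
    mapping keyed by group label.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"acute-orthopedic": 10, "acute-cardiac": 24, "chronic-IIPT": 28}
    )
    study_days: _PerGroup = field(
        default_factory=lambda: {"acute-orthopedic": 20, "acute-cardiac": 20, "chronic-IIPT": 24}
    )
    wear_prob_day: _PerGroup = field(
        default_factory=lambda: {"acute-orthopedic": 0.88, "acute-cardiac": 0.78, "chronic-IIPT": 0.93}
    )
    wear_prob_night: _PerGroup = field(
        default_factory=lambda: {"acute-orthopedic": 0.90, "acute-cardiac": 0.85, "chronic-IIPT": 0.94}
    )
    mean_sleep_minutes: float = 480.0
    charge_interval_days: int = 7
    charge_gap_minutes: int = 90
    sync_interval_days: tuple[int, int] = (2, 3)
    clip_mode_prob: float = 0.0
    storage_window_days: int = 7
    seed: int = 0
    wear_model: str = "bouts"  # "bouts" | "iid"
    nonwear_bout_mean_minutes: float = 45.0
    tz_offset_minutes: int = 0
    acceptability_profiles: Mapping[str, AcceptabilityProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        for g in self.n_per_group:
            validate_group(g)
        self._study_days = {g: int(v) for g, v in _per_group(self.study_days, self.groups, "study_days").items()}
        self._wear_day = _per_group(self.wear_prob_day, self.groups, "wear_prob_day")
        self._wear_night = _per_group(self.wear_prob_night, self.groups, "wear_prob_night")
        for name, mapping in (("wear_prob_day", self._wear_day), ("wear_prob_night", self._wear_night)):
            for g, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{g}] must lie in [0, 1], got {p}")
        if not 0.0 <= self.clip_mode_prob <= 1.0:
            raise ValueError("clip_mode_prob must lie in [0, 1]")
        for g, d in self._study_days.items():
            if d < 2:
                raise ValueError("study_days must be >= 2")
        if self.storage_window_days < 1:
            raise ValueError("storage_window_days must be >= 1")
        if self.wear_model not in ("bouts", "iid"):
            raise ValueError("wear_model must be 'bouts' or 'iid'")
        lo, hi = self.sync_interval_days
        if not (1 <= lo <= hi):
            raise ValueError("sync_interval_days must satisfy 1 <= lo <= hi")
        if self.charge_gap_minutes < 0 or self.charge_interval_days < 1:
            raise ValueError("invalid charging parameters")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUPS if g in self.n_per_group)

    def study_days_for(self, group: str) -> int:
        return self._study_days[group]

    def wear_day_for(self, group: str) -> float:
        return self._wear_day[group]

    def wear_night_for(self, group: str) -> float:
        return self._wear_night[group]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sync_interval_days" in raw:
            raw["sync_interval_days"] = tuple(raw["sync_interval_days"])
        if "acceptability_profiles" in raw:
            raw["acceptability_profiles"] = {
                g: AcceptabilityProfile(**p) for g, p in raw["acceptability_profiles"].items()
            }
        return cls(**raw)


def _participant_rng(seed: int, group: str, index: int) -> np.random.Generator:
    # Stable hash of (seed, group, index): insertion order of participants in
    # the cohort never perturbs an individual's stream.
    return np.random.default_rng([int(seed), zlib.crc32(group.encode()), int(index)])


def _sample_worn(
    rng: np.random.Generator,
    p_minute: np.ndarray,
    model: str,
    nonwear_mean: float,
) -> np.ndarray:
    """Realize a worn/not-worn boolean series from per-minute target probabilities."""
    n = len(p_minute)
    if model == "iid":
        return rng.random(n) < p_minute
    worn = np.zeros(n, dtype=bool)
    i = 0
    state = bool(rng.random() < p_minute[0])
    while i < n:
        p = p_minute[i]
        if p >= 1.0:
            worn[i] = True
            i += 1
            state = True
            continue
        if p <= 0.0:
            worn[i] = False
            i += 1
            state = False
            continue
        if state:
            mean = max(1.0, nonwear_mean * p / (1.0 - p))
        else:
            mean = max(1.0, nonwear_mean)
        length = int(rng.geometric(1.0 / mean))
        worn[i : i + length] = state
        i += length
        state = not state
    return worn


def _sleep_schedule(
    rng: np.random.Generator,
    start: pd.Timestamp,
    end: pd.Timestamp,
    mean_sleep_minutes: float,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """One candidate sleep interval per night between consecutive study dates."""
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    first_midnight = pd.Timestamp(start.date()) + pd.Timedelta(days=1)
    night = first_midnight
    while night <= pd.Timestamp(end.date()):
        onset = night - pd.Timedelta(minutes=int(rng.integers(30, 150)))
        dur = float(np.clip(rng.normal(mean_sleep_minutes, 40.0), 300, 660))
        dur = int(round(dur / 2) * 2)  # even minutes -> whole 30-s slots
        wake = onset + pd.Timedelta(minutes=dur)
        if onset >= start and wake <= end:
            intervals.append((onset, wake))
        night += pd.Timedelta(days=1)
    return intervals


def _stage_runs(rng: np.random.Generator, start: pd.Timestamp, end: pd.Timestamp) -> list[StageRun]:
    slots = int((end - start) / pd.Timedelta(seconds=30))
    runs: list[StageRun] = []
    cursor = start
    remaining = slots
    levels = np.array(["light", "deep", "rem", "wake"])
    probs = np.array([0.50, 0.22, 0.20, 0.08])
    while remaining > 0:
        level = str(rng.choice(levels, p=probs))
        run_slots = int(min(remaining, rng.integers(6, 61)))
        runs.append(StageRun(cursor, level, run_slots * 30))
        cursor += pd.Timedelta(seconds=run_slots * 30)
        remaining -= run_slots
    return runs


def generate_participant(group: str, cfg: SimConfig, participant_index: int) -> ParticipantRecord:
    """Generate one participant's full record, including ground-truth wear.

    The stream covers a contiguous minute grid from enrollment start (mid
    morning of day 0) to study end (around midday of day ``study_days + 1``),
    so that after partial-edge trimming exactly ``study_days`` full calendar
    days remain.
    """
    validate_group(group)
    rng = _participant_rng(cfg.seed, group, participant_index)
    n_days = cfg.study_days_for(group)

    start_date = _BASE_DATE + dt.timedelta(days=int(rng.integers(0, 28)))
    start = pd.Timestamp(start_date) + pd.Timedelta(minutes=int(rng.integers(8 * 60, 12 * 60)))
    end = pd.Timestamp(start_date) + pd.Timedelta(
        days=n_days + 1, minutes=int(rng.integers(11 * 60, 16 * 60))
    )
    grid = pd.date_range(start, end, freq="min")
    n = len(grid)

    sleep_intervals = _sleep_schedule(rng, start, end, cfg.mean_sleep_minutes)
    asleep = np.zeros(n, dtype=bool)
    for onset, wake in sleep_intervals:
        i0 = int((onset.ceil("min") - start) / pd.Timedelta(minutes=1))
        i1 = int((wake - start) / pd.Timedelta(minutes=1))
        asleep[i0:i1] = True

    p_minute = np.where(asleep, cfg.wear_night_for(group), cfg.wear_day_for(group))
    worn = _sample_worn(rng, p_minute, cfg.wear_model, cfg.nonwear_bout_mean_minutes)

    # Charging windows force the device off-wrist on a fixed evening cadence.
    if cfg.charge_gap_minutes > 0:
        day = cfg.charge_interval_days
        while day <= n_days + 1:
            gap_start = pd.Timestamp(start_date) + pd.Timedelta(days=day, hours=19)
            i0 = int(max(0, (gap_start - start) / pd.Timedelta(minutes=1)))
            i1 = min(n, i0 + cfg.charge_gap_minutes)
            worn[i0:i1] = False
            day += cfg.charge_interval_days

    rest_hr = float(np.clip(rng.normal(72.0, 6.0), 55.0, 95.0))
    base = np.where(asleep, rest_hr - 12.0, rest_hr + 8.0)
    hr = np.exp(np.log(base) + rng.normal(0.0, 0.06, size=n))
    hr = np.clip(np.round(hr), 25, 250)
    heart_rate = np.where(worn, hr, np.nan)

    sedentary = rng.random(n) < 0.60
    step_counts = rng.poisson(28.0, size=n).astype(float)
    step_counts[sedentary | asleep] = 0.0
    steps = np.where(worn, step_counts, np.nan)

    sleep_periods: list[SleepPeriod] = []
    for onset, wake in sleep_intervals:
        i0 = int((onset.ceil("min") - start) / pd.Timedelta(minutes=1))
        i1 = int((wake - start) / pd.Timedelta(minutes=1))
        if worn[i0:i1].any():  # a fully off-wrist night produces no sleep log
            sleep_periods.append(SleepPeriod(onset, wake, _stage_runs(rng, onset, wake)))

    sync_events: list[pd.Timestamp] = []
    lo, hi = cfg.sync_interval_days
    day = int(rng.integers(lo, hi + 1))
    while day <= n_days:
        sync_events.append(pd.Timestamp(start_date) + pd.Timedelta(days=day, hours=20))
        day += int(rng.integers(lo, hi + 1))
    sync_events.append(end)  # final staff download at study end

    epochs = pd.DataFrame(
        {
            "timestamp": grid,
            "heart_rate": heart_rate,
            "steps": steps,
            "device_mode": "wrist",
        }
    )
    profile = cfg.acceptability_profiles.get(group)
    acceptability = _draw_acceptability(rng, group, profile) if profile else None

    record = ParticipantRecord(
        participant_id=f"wc-{_GROUP_TAGS[group]}-{participant_index:03d}",
        group=group,
        device_profile=_GROUP_DEVICES[group],
        epochs=epochs,
        sleep=sleep_periods,
        sync_events=sync_events,
        acceptability=acceptability,
        tz_offset_minutes=cfg.tz_offset_minutes,
        truth_worn=pd.Series(worn, index=grid, name="worn"),
    )

    if cfg.clip_mode_prob > 0:
        all_days = pd.date_range(start.normalize(), end.normalize(), freq="D").date
        clip_days = {d for d in all_days if rng.random() < cfg.clip_mode_prob}
        if clip_days:
            record = inject_clip_mode(record, clip_days)

    from .ingest import build_day_summaries  # device-side daily summaries

    record.day_summaries = build_day_summaries(record)
    record = apply_storage_truncation(record, record.sync_events, cfg.storage_window_days)
    return record


def _draw_acceptability(
    rng: np.random.Generator, group: str, profile: AcceptabilityProfile
) -> AcceptabilityResponse:
    def item(mean: float, sd: float) -> float:
        return float(np.clip(round(rng.normal(mean, sd), 1), 0.0, 10.0))

    sleep_item = None
    if group == CHRONIC_GROUP and profile.sleep_disturbance_mean is not None:
        sleep_item = item(profile.sleep_disturbance_mean, profile.sleep_disturbance_sd or 0.0)
    adverse = bool(rng.random() < profile.adverse_prob)
    return AcceptabilityResponse(
        comfort=item(profile.comfort_mean, profile.comfort_sd),
        burden=item(profile.burden_mean, profile.burden_sd),
        sleep_disturbance=sleep_item,
        adverse_reaction=adverse,
        adverse_text="mild wrist irritation" if adverse else None,
    )


def inject_clip_mode(record: ParticipantRecord, days: Iterable[dt.date]) -> ParticipantRecord:
    """Simulate clip-mode carry on the given local calendar days.

    Clip mode deactivates the optical skin sensor: heart-rate samples are
    removed and sleep periods overlapping an affected day are suppressed;
    step counts are retained.
    """
    days = {d if isinstance(d, dt.date) else pd.Timestamp(d).date() for d in days}
    if not days:
        return record.copy()
    start_day = record.to_local(record.stream_start).date()
    end_day = record.to_local(record.stream_end).date()
    for d in sorted(days):
        if not (start_day <= d <= end_day):
            raise ValueError(f"clip-mode date {d} outside study window {start_day}..{end_day}")

    out = record.copy()
    local_dates = (out.epochs["timestamp"] + out.local_offset).dt.date
    affected = local_dates.isin(days).to_numpy()
    out.epochs.loc[affected, "heart_rate"] = np.nan
    out.epochs.loc[affected, "device_mode"] = "clip"

    def overlaps_clip(p: SleepPeriod) -> bool:
        d0 = record.to_local(p.start).date()
        d1 = record.to_local(p.end).date()
        span = {d0 + dt.timedelta(days=k) for k in range((d1 - d0).days + 1)}
        return bool(span & days)

    out.sleep = [p for p in out.sleep if not overlaps_clip(p)]
    return out


def apply_storage_truncation(
    record: ParticipantRecord,
    sync_times: Iterable[pd.Timestamp],
    storage_window_days: int = 7,
) -> ParticipantRecord:
    """Drop minute samples that aged out of the on-device buffer before a sync.

    A minute sample survives iff some sync happens no later than
    ``storage_window_days`` after it; otherwise only the daily summary
    remains.  Daily summaries are computed first so one survives for every
    study day regardless of minute-level loss.
    """
    syncs = sorted(pd.Timestamp(s) for s in sync_times)
    out = record.copy()
    if out.day_summaries is None:
        from .ingest import build_day_summaries

        out.day_summaries = build_day_summaries(record)

    ts = out.epochs["timestamp"].to_numpy()
    if len(ts) == 0:
        return out
    window = np.timedelta64(storage_window_days, "D")
    if not syncs:
        kept = np.zeros(len(ts), dtype=bool)
    else:
        sync_arr = np.array([np.datetime64(s) for s in syncs])
        idx = np.searchsorted(sync_arr, ts, side="left")
        kept = idx < len(sync_arr)
        covering = sync_arr[np.minimum(idx, len(sync_arr) - 1)]
        kept &= (covering - ts) <= window
    out.epochs = out.epochs.loc[kept].reset_index(drop=True)
    return out


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Generate ``cfg.n_per_group[g]`` records per group plus survey responses."""
    if not any(cfg.n_per_group.values()):
        raise ValueError("n_per_group must be positive for at least one group")
    records = [
        generate_participant(group, cfg, i)
        for group in cfg.groups
        for i in range(int(cfg.n_per_group[group]))
    ]
    return Cohort(records=records)


def write_ground_truth(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write the per-minute ground-truth worn annotation as CSV (UTC ISO-8601)."""
    frames = []
    for rec in cohort.records:
        if rec.truth_worn is None:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "timestamp": rec.truth_worn.index.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "worn": rec.truth_worn.to_numpy().astype(int),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "timestamp", "worn"]
    )
    table.to_csv(path, index=False)
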
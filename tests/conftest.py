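from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wearcomply.synth import SimConfig, generate_cohort
from wearcomply.types import ParticipantRecord, SleepPeriod, StageRun


def make_epochs(rows):
    """Build an epoch DataFrame from (timestamp, heart_rate, steps[, mode]) tuples."""
    ts, hr, steps, mode = [], [], [], []
    for row in rows:
        ts.append(pd.Timestamp(row[0]))
        hr.append(np.nan if row[1] is None else float(row[1]))
        steps.append(np.nan if row[2] is None else float(row[2]))
        mode.append(row[3] if len(row) > 3 else "wrist")
    return pd.DataFrame({"timestamp": ts, "heart_rate": hr, "steps": steps, "device_mode": mode})


def make_record(epochs, sleep=(), group="acute-cardiac", pid="p1", syncs=(), **kwargs):
    return ParticipantRecord(
        participant_id=pid,
        group=group,
        device_profile="charge3",
        epochs=epochs,
        sleep=list(sleep),
        sync_events=[pd.Timestamp(s) for s in syncs],
        **kwargs,
    )


def uniform_sleep(start, end, level="light"):
    """A sleep period whose stage runs are a single uniform level."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    seconds = int((end - start).total_seconds())
    return SleepPeriod(start, end, [StageRun(start, level, seconds)])


def grid_record(start, n_minutes, worn, sleep=(), **kwargs):
    """Record over a contiguous minute grid; ``worn`` is a boolean sequence.

    Worn minutes carry heart rate; unworn minutes carry no samples at all.
    """
    start = pd.Timestamp(start)
    grid = pd.date_range(start, periods=n_minutes, freq="min")
    worn = np.asarray(worn, dtype=bool)
    hr = np.where(worn, 70.0, np.nan)
    steps = np.where(worn, 0.0, np.nan)
    epochs = pd.DataFrame(
        {"timestamp": grid, "heart_rate": hr, "steps": steps, "device_mode": "wrist"}
    )
    return make_record(epochs, sleep=sleep, **kwargs)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        seed=11,
        n_per_group={"acute-orthopedic": 2, "acute-cardiac": 2, "chronic-IIPT": 2},
        study_days=6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def clean_cfg():
    """Artifact-free config: no clip mode, no charging gaps, frequent syncs."""
    return SimConfig(
        seed=23,
        n_per_group={"acute-orthopedic": 2, "acute-cardiac": 2, "chronic-IIPT": 2},
        study_days=6,
        charge_gap_minutes=0,
        clip_mode_prob=0.0,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_cfg):
    return generate_cohort(clean_cfg)
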
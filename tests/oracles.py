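"""Independent brute-force oracles used to check the package implementations.

Everything here is deliberately naive (loops, enumeration) and shares no code
with the package paths it validates.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def brute_worn_minute(heart_rate, steps) -> bool:
    """Per-minute wear rule evaluated directly."""
    if heart_rate is not None and not (isinstance(heart_rate, float) and np.isnan(heart_rate)):
        return True
    if steps is None or (isinstance(steps, float) and np.isnan(steps)):
        return False
    return steps > 0


def brute_longest_run(values) -> int:
    best = cur = 0
    for v in values:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def brute_u_statistic(a, b) -> float:
    """U for the first sample: #(a_i > b_j) pairs + half the ties."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_exact_mw_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumeration over all labelings.

    Tie-free inputs only.  Counts labelings whose U is at least as extreme
    (in either tail) as the observed U.
    """
    a, b = list(a), list(b)
    n_a, n_b = len(a), len(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires tie-free input"
    u_obs = brute_u_statistic(a, b)
    u_extreme = min(u_obs, n_a * n_b - u_obs)
    count = 0
    idx = range(n_a + n_b)
    for chosen in combinations(idx, n_a):
        chosen = set(chosen)
        aa = [pooled[i] for i in idx if i in chosen]
        bb = [pooled[i] for i in idx if i not in chosen]
        u = brute_u_statistic(aa, bb)
        if min(u, n_a * n_b - u) <= u_extreme + 1e-12:
            count += 1
    return count / comb(n_a + n_b, n_a)


def brute_sleep_minute_mask(period) -> dict[pd.Timestamp, bool]:
    """Minute-by-minute evaluation of the >=1 non-wake 30-s record rule."""
    slots = []
    for run in period.stage_runs:
        t = run.start
        for _ in range(run.seconds // 30):
            slots.append((t, run.level))
            t += pd.Timedelta(seconds=30)
    out: dict[pd.Timestamp, bool] = {}
    for t, level in slots:
        minute = t.floor("min")
        out[minute] = out.get(minute, False) or (level != "wake")
    return out


def brute_streak_flags(pattern, threshold) -> list[int]:
    """Indices where a noncompliant run first reaches ``threshold``.

    ``pattern`` is a sequence of booleans (True = compliant).
    """
    hits = []
    run = 0
    for i, compliant in enumerate(pattern):
        run = 0 if compliant else run + 1
        if run == threshold:
            hits.append(i)
    return hits
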
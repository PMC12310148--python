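"""Acceptability and feasibility statistics.

Group comparisons use the pooled-variance (Student) two-sample t test with
df = n1 + n2 - 2 (Welch available behind a flag) and the Mann-Whitney U test
with midranks; the reported U belongs to the first-listed sample, and the
two-sided p value is exact by enumeration for small tie-free samples and a
tie-corrected normal approximation without continuity correction otherwise.
No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from ._util import pct, round_half_up
from .compliance import ComplianceSummary, aggregate_group
from .types import ACUTE_GROUPS, CHRONIC_GROUP, AcceptabilityResponse, Cohort

logger = logging.getLogger("wearcomply.stats")

__all__ = [
    "TestResult",
    "GroupSummary",
    "AdverseRates",
    "summarize_acceptability",
    "adverse_rates",
    "pooled_t_test",
    "pooled_t_from_summary",
    "mann_whitney_u",
    "run_table_suite",
]

ITEMS = ("comfort", "burden", "sleep_disturbance")

_EXACT_MAX_PRODUCT = 400


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "pooled_t" | "welch_t" | "mann_whitney_u"
    df: Optional[float] = None
    statistic_other: Optional[float] = None  # complementary U for the second sample

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value must lie in [0, 1]")
        if (self.df is not None) != (self.method in ("pooled_t", "welch_t")):
            raise ValueError("df present iff a t-family method")


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    assessed: bool = True

    def as_dict(self) -> dict:
        if not self.assessed:
            return {"label": self.label, "assessed": False}
        return {
            "label": self.label,
            "n": self.n,
            "mean": round_half_up(self.mean, 2),
            "sd": round_half_up(self.sd, 2),
        }


def summarize_acceptability(
    responses: Sequence[AcceptabilityResponse], label: str = ""
) -> dict[str, GroupSummary]:
    """Sample mean and SD (n-1 denominator) per survey item.

    An item absent for every respondent yields a not-assessed marker rather
    than a summary.
    """
    out: dict[str, GroupSummary] = {}
    for item in ITEMS:
        values = [getattr(r, item) for r in responses if getattr(r, item) is not None]
        if not values:
            out[item] = GroupSummary(label=f"{label}:{item}", n=0, assessed=False)
            continue
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[item] = GroupSummary(label=f"{label}:{item}", n=len(arr), mean=float(arr.mean()), sd=sd)
    return out


@dataclass(frozen=True)
class AdverseRates:
    per_group_pct_none: dict[str, float]  # one decimal
    per_group_counts: dict[str, tuple[int, int]]  # (reporters, total)
    pooled_pct_any: float  # two decimals
    pooled_counts: tuple[int, int]


def adverse_rates(
    responses_by_group: Mapping[str, Sequence[Union[AcceptabilityResponse, bool]]]
) -> AdverseRates:
    """Per-group percent reporting no adverse reaction and pooled percent any."""
    pct_none: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    pooled_any = 0
    pooled_n = 0
    for group, responses in responses_by_group.items():
        flags = [
            bool(r.adverse_reaction) if isinstance(r, AcceptabilityResponse) else bool(r)
            for r in responses
        ]
        n = len(flags)
        if n == 0:
            raise ValueError(f"zero adverse-rate denominator for group {group!r}")
        reporters = sum(flags)
        counts[group] = (reporters, n)
        pct_none[group] = pct(n - reporters, n, ndigits=1)
        pooled_any += reporters
        pooled_n += n
    return AdverseRates(
        per_group_pct_none=pct_none,
        per_group_counts=counts,
        pooled_pct_any=pct(pooled_any, pooled_n, ndigits=2),
        pooled_counts=(pooled_any, pooled_n),
    )


# ---------------------------------------------------------------------------
# two-sample tests

def pooled_t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Pooled-variance t from (mean, sd, n) summaries; sign is b minus a."""
    if n_a < 2 or n_b < 2:
        raise ValueError("pooled t requires n >= 2 per group")
    if not (math.isfinite(sd_a) and math.isfinite(sd_b)):
        raise ValueError("sds must be finite")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled_var == 0.0:
        if mean_a == mean_b:
            return TestResult(statistic=0.0, p_value=1.0, method="pooled_t", df=df)
        raise ValueError("zero pooled variance with unequal means")
    se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    t = (mean_b - mean_a) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=t, p_value=float(min(p, 1.0)), method="pooled_t", df=df)


def pooled_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sample t test on raw samples; sign convention is second minus first."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t test requires n >= 2 per group")
    if welch:
        res = sps.ttest_ind(b, a, equal_var=False)
        return TestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue), method="welch_t",
            df=float(res.df),
        )
    return pooled_t_from_summary(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
    )


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Mann-Whitney U with midranks; U is reported for the first-listed sample.

    The two-sided p value is exact (enumeration) when ``n_a * n_b <= 400``
    and the pooled sample has no ties, otherwise a tie-corrected normal
    approximation without continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(a) * len(b) <= _EXACT_MAX_PRODUCT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    u_a = float(res.statistic)
    p = float(res.pvalue)
    if has_ties and math.isnan(p):  # all observations identical -> zero variance
        p = 1.0
    return TestResult(
        statistic=u_a,
        p_value=min(p, 1.0),
        method="mann_whitney_u",
        statistic_other=len(a) * len(b) - u_a,
    )


# ---------------------------------------------------------------------------
# full table grid

def _test_dict(res: Optional[TestResult]) -> Optional[dict]:
    if res is None:
        return None
    out = {"statistic": res.statistic, "p_value": res.p_value, "method": res.method}
    if res.df is not None:
        out["df"] = res.df
    if res.statistic_other is not None:
        out["statistic_other"] = res.statistic_other
    return out


def _group_stats_dict(stats) -> dict:
    out = {
        "n": stats.n,
        "total_compliant_days": stats.totals.compliant_days,
        "total_study_days": stats.totals.study_days,
        "median_compliant_days": stats.median_compliant_days,
        "range_compliant_days": list(stats.range_compliant_days),
        "median_study_days": stats.median_study_days,
        "range_study_days": list(stats.range_study_days),
        "median_day_rate": stats.median_day_rate,
        "range_day_rate": list(stats.range_day_rate),
        "n_night": stats.n_night,
        "total_compliant_nights": stats.totals.compliant_nights,
        "total_study_nights": stats.totals.study_nights,
    }
    if stats.n_night:
        out.update(
            {
                "median_compliant_nights": stats.median_compliant_nights,
                "median_study_nights": stats.median_study_nights,
                "median_night_rate": stats.median_night_rate,
                "range_night_rate": list(stats.range_night_rate),
            }
        )
    return out


def run_table_suite(
    cohort: Cohort,
    summaries: Sequence[ComplianceSummary],
    min_group_size: int = 2,
) -> dict:
    """Emit the full acceptability/feasibility grid for a scored cohort.

    Structure mirrors the three reporting tables: per-group acceptability
    means/SDs with orthopedic-vs-cardiac and acute-vs-chronic t tests, then
    day and night compliance totals/medians/ranges with the corresponding
    Mann-Whitney comparisons.  Comparisons involving a group below
    ``min_group_size`` are omitted with a warning.
    """
    ortho, cardiac = ACUTE_GROUPS
    resp = {
        g: [r.acceptability for r in cohort.by_group(g) if r.acceptability is not None]
        for g in (ortho, cardiac, CHRONIC_GROUP)
    }
    resp_acute = resp[ortho] + resp[cardiac]

    def maybe_t(a: list[float], b: list[float], what: str) -> Optional[TestResult]:
        if len(a) < min_group_size or len(b) < min_group_size:
            logger.warning("comparison omitted (%s): group below %d", what, min_group_size)
            return None
        return pooled_t_test(a, b)

    def item_values(responses, item):
        return [getattr(r, item) for r in responses if getattr(r, item) is not None]

    acceptability = {
        "orthopedic": {k: v.as_dict() for k, v in summarize_acceptability(resp[ortho], "orthopedic").items()},
        "cardiac": {k: v.as_dict() for k, v in summarize_acceptability(resp[cardiac], "cardiac").items()},
        "acute_total": {k: v.as_dict() for k, v in summarize_acceptability(resp_acute, "acute").items()},
        "chronic": {k: v.as_dict() for k, v in summarize_acceptability(resp[CHRONIC_GROUP], "chronic").items()},
        "tests": {
            "ortho_vs_cardiac": {
                item: _test_dict(
                    maybe_t(item_values(resp[ortho], item), item_values(resp[cardiac], item), item)
                )
                for item in ("comfort", "burden")
            },
            "acute_vs_chronic": {
                item: _test_dict(
                    maybe_t(item_values(resp_acute, item), item_values(resp[CHRONIC_GROUP], item), item)
                )
                for item in ("comfort", "burden")
            },
        },
        "adverse": None,
    }
    by_group_resp = {
        "acute": [r for r in resp_acute],
        "chronic": list(resp[CHRONIC_GROUP]),
    }
    if all(by_group_resp.values()):
        rates = adverse_rates(by_group_resp)
        acceptability["adverse"] = {
            "pct_none": rates.per_group_pct_none,
            "counts": {g: list(c) for g, c in rates.per_group_counts.items()},
            "pooled_pct_any": rates.pooled_pct_any,
        }

    sub = {g: [s for s in summaries if s.group == g] for g in (ortho, cardiac, CHRONIC_GROUP)}
    acute = sub[ortho] + sub[cardiac]
    groups = {
        "orthopedic": sub[ortho],
        "cardiac": sub[cardiac],
        "acute_total": acute,
        "chronic": sub[CHRONIC_GROUP],
    }
    compliance: dict = {}
    for name, rows in groups.items():
        compliance[name] = _group_stats_dict(aggregate_group(rows, label=name)) if rows else None

    def maybe_u(a: list[float], b: list[float], what: str) -> Optional[TestResult]:
        if len(a) < min_group_size or len(b) < min_group_size:
            logger.warning("comparison omitted (%s): group below %d", what, min_group_size)
            return None
        return mann_whitney_u(a, b)

    day_tests = {
        "ortho_vs_cardiac_rate": _test_dict(
            maybe_u([s.day_rate_pct for s in sub[ortho]], [s.day_rate_pct for s in sub[cardiac]], "day rate o/c")
        ),
        "acute_vs_chronic_rate": _test_dict(
            maybe_u([s.day_rate_pct for s in acute], [s.day_rate_pct for s in sub[CHRONIC_GROUP]], "day rate a/c")
        ),
        "acute_vs_chronic_compliant_days": _test_dict(
            maybe_u([s.compliant_days for s in acute], [s.compliant_days for s in sub[CHRONIC_GROUP]], "compliant days")
        ),
        "acute_vs_chronic_study_days": _test_dict(
            maybe_u([s.study_days for s in acute], [s.study_days for s in sub[CHRONIC_GROUP]], "study days")
        ),
    }

    def night_rates(rows):
        return [s.night_rate_pct for s in rows if s.study_nights > 0]

    night_tests = {
        "ortho_vs_cardiac_rate": _test_dict(
            maybe_u(night_rates(sub[ortho]), night_rates(sub[cardiac]), "night rate o/c")
        ),
        "acute_vs_chronic_rate": _test_dict(
            maybe_u(night_rates(acute), night_rates(sub[CHRONIC_GROUP]), "night rate a/c")
        ),
    }
    return {
        "acceptability": acceptability,
        "day_compliance": {"groups": compliance, "tests": day_tests},
        "night_compliance": {"tests": night_tests},
    }
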
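"""Longitudinal group comparison and the histology positivity statistic.

The group comparison follows an endpoint-gated closed testing procedure:
a two-sided pooled-variance (Student) t-test is run first at the a-priori
endpoint week (where the maximum difference is predicted, typically the
last week); only if that p-value is below alpha does testing step
backward through earlier weeks, stopping at the first non-significant
one.  The earliest significant week is the start of the unbroken
significant run ending at the endpoint.  No further multiplicity
correction is applied beyond this gate.

By default the two DRGs of an animal are averaged to one value per
animal per week before testing (animals, not ganglia, are the
independent units); ``per_drg=True`` switches to per-DRG observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClosedTestResult",
    "TTestResult",
    "records_to_table",
    "pool_groups",
    "student_t",
    "closed_testing",
    "positivity_percent",
]

TABLE_COLUMNS = ["animal_id", "side", "timepoint", "group", "csa"]


def records_to_table(records) -> pd.DataFrame:
    """Flatten CSARecord objects into a longitudinal DataFrame."""
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "side": r.side,
                "timepoint": r.timepoint,
                "group": r.group,
                "csa": r.csa,
            }
            for r in records
        ]
    )


def pool_groups(
    table: pd.DataFrame, groups_to_pool: list[str], pooled_name: str
) -> pd.DataFrame:
    """Relabel the listed groups to one pooled group; rows untouched otherwise."""
    unknown = set(groups_to_pool) - set(table["group"].unique())
    if unknown:
        raise ValueError(f"unknown group(s): {sorted(unknown)}")
    out = table.copy()
    out.loc[out["group"].isin(groups_to_pool), "group"] = pooled_name
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # all values identical in both samples


def student_t(sample_a, sample_b, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test, pooled-variance (Student) by default.

    Degenerate input (zero variance in both samples and equal means) is
    flagged and returns p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, df=df, degenerate=True)
        return TTestResult(t=np.inf if a.mean() > b.mean() else -np.inf,
                           p=0.0, df=df, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=int(res.df))


@dataclass
class ClosedTestResult:
    group_a: str
    group_b: str
    endpoint_week: float
    endpoint_p: float
    earliest_significant_week: float | None
    per_week_p: dict[float, float] = field(default_factory=dict)
    alpha: float = 0.05


def _per_animal(table: pd.DataFrame, per_drg: bool) -> pd.DataFrame:
    if per_drg:
        return table
    return (
        table.groupby(["animal_id", "group", "timepoint"], as_index=False)["csa"]
        .mean()
    )


def closed_testing(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    weeks_ordered: list[float],
    endpoint_week: float | None = None,
    alpha: float = 0.05,
    per_drg: bool = False,
    welch: bool = False,
) -> ClosedTestResult:
    """Endpoint-gated retrospective closed testing of two groups.

    Tests group_a vs group_b at ``endpoint_week`` (default: last week);
    if significant, steps backward through ``weeks_ordered`` while
    p < alpha, stopping at the first failure.  All computed p-values are
    returned for audit; ``earliest_significant_week`` is ``None`` when
    the endpoint test fails the gate.
    """
    if endpoint_week is None:
        endpoint_week = weeks_ordered[-1]
    if endpoint_week not in weeks_ordered:
        raise ValueError("endpoint week not in the week grid")
    data = _per_animal(table, per_drg)

    def samples(week: float):
        wk = data[data["timepoint"] == week]
        a = wk.loc[wk["group"] == group_a, "csa"].to_numpy()
        b = wk.loc[wk["group"] == group_b, "csa"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"missing group-week cell at week {week}")
        return a, b

    per_week_p: dict[float, float] = {}
    res = student_t(*samples(endpoint_week), welch=welch)
    per_week_p[endpoint_week] = res.p
    if res.p >= alpha:
        return ClosedTestResult(group_a, group_b, endpoint_week, res.p,
                                None, per_week_p, alpha)

    earliest = endpoint_week
    idx = weeks_ordered.index(endpoint_week) - 1
    while idx >= 0:
        week = weeks_ordered[idx]
        p = student_t(*samples(week), welch=welch).p
        per_week_p[week] = p
        if p >= alpha:
            break
        earliest = week
        idx -= 1
    return ClosedTestResult(group_a, group_b, endpoint_week,
                            per_week_p[endpoint_week], earliest,
                            per_week_p, alpha)


def positivity_percent(positive_px: int, total_px: int) -> float:
    """Stained-pixel positivity: 100 x positive / total analyzed pixels."""
    if total_px <= 0:
        raise ValueError("total pixel count must be positive")
    if not 0 <= positive_px <= total_px:
        raise ValueError("positive pixel count must lie in [0, total]")
    return 100.0 * positive_px / total_px
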
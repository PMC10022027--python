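"""Rolling site-months up over the US fiscal calendar and geography.

The fiscal year (FY) runs 1 October - 30 September and is labelled by the
calendar year in which it ends: FY2015 begins 2014-10-01.  Quarters are
Q1 = Oct-Dec, Q2 = Jan-Mar, Q3 = Apr-Jun, Q4 = Jul-Sep; half-years are
H1 = Oct-Mar, H2 = Apr-Sep.

Aggregation rules
-----------------
* additive fields (targets, performance counts, days of operation) are
  summed within a bucket;
* staffing and beds are stocks, not flows: they are summed across sites
  within a month, then averaged across the months of the bucket
  (``staffing_rule="mean"``; ``"last"`` takes the final month instead);
* capacity is recomputed from the member site-months (daily capacity x
  that month's days of operation, summed) — never from displayed
  roundings;
* ratio indicators are recomputed from aggregated numerators and
  denominators (U = sum(V) / sum(C)) — never averaged across members,
  which would weight small sites like large ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from sitecap.data_model import CapacityParams, MonthlyRecord, SiteProfile
from sitecap.indicators import (
    capacity_over_period,
    compute_indicator_set,
    current_capacity_daily,
    optimum_capacity_daily,
    staffing_gap,
)

GRANULARITIES = ("month", "quarter", "half_year", "year")
LEVELS = ("site", "fixed_site_group", "health_zone", "province", "region",
          "all")


@dataclass(frozen=True, order=True)
class Period:
    """A fiscal-calendar time bucket.

    ``index_within_year`` is the month (1-12, counted from October),
    quarter (1-4), half (1-2) or 1 for whole years.  Ordering follows
    calendar time.
    """

    fiscal_year: int
    index_within_year: int
    granularity: str

    def __post_init__(self):
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"granularity must be one of {GRANULARITIES}")

    @property
    def label(self) -> str:
        fy = f"FY{self.fiscal_year % 100:02d}"
        if self.granularity == "year":
            return fy
        if self.granularity == "quarter":
            return f"{fy} Q{self.index_within_year}"
        if self.granularity == "half_year":
            return f"{fy} H{self.index_within_year}"
        # month: recover the calendar month (index 1 = October)
        m = (self.index_within_year + 9 - 1) % 12 + 1
        y = self.fiscal_year - 1 if m >= 10 else self.fiscal_year
        return f"{y:04d}-{m:02d}"

    def __str__(self) -> str:  # pragma: no cover
        return self.label


def to_period(month: str, granularity: str = "quarter") -> Period:
    """Map an ISO "YYYY-MM" month to its fiscal-calendar period."""
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    y, m = int(month[:4]), int(month[5:7])
    fy = y + 1 if m >= 10 else y
    fiscal_month = (m - 10) % 12 + 1  # October = 1
    if granularity == "month":
        idx = fiscal_month
    elif granularity == "quarter":
        idx = (fiscal_month - 1) // 3 + 1
    elif granularity == "half_year":
        idx = (fiscal_month - 1) // 6 + 1
    else:
        idx = 1
    return Period(fiscal_year=fy, index_within_year=idx,
                  granularity=granularity)


# ---------------------------------------------------------------------------


def group_key(profile: SiteProfile, level: str) -> str:
    """The grouping label a site contributes to at an aggregation level."""
    if level == "site":
        return profile.site_name
    if level == "fixed_site_group":
        return profile.parent_fixed_site or profile.site_name
    if level == "health_zone":
        return profile.health_zone
    if level == "province":
        return profile.province
    if level == "region":
        return profile.region or profile.province
    if level == "all":
        return "all"
    raise ValueError(f"unknown aggregation level {level!r}")


_ADDITIVE = [
    "target", "days_of_operation", "performed", "reached", "seeking",
    "followup_48h", "followup_7d", "followup_6w",
    "ae_mild", "ae_moderate", "ae_severe",
    "sti_diagnosed", "sti_treated_circumcised",
    "hiv_tests", "hiv_pos_referred",
    "current_capacity", "optimum_capacity",
]
_STOCK = ["providers", "trained_assistants", "other_nurses", "mobilizers",
          "counselors", "beds"]


def records_frame(profiles: Sequence[SiteProfile],
                  records: Sequence[MonthlyRecord],
                  params: Optional[CapacityParams] = None) -> pd.DataFrame:
    """One row per site-month with derived totals and monthly capacities.

    ``current_capacity`` / ``optimum_capacity`` are the month's capacities:
    daily capacity (given that site's task arrangements) times the month's
    reported days of operation.
    """
    params = params or CapacityParams()
    by_name = {p.site_name: p for p in profiles}
    rows: List[Dict] = []
    for r in records:
        p = by_name.get(r.site_name)
        if p is None:
            raise KeyError(f"record references unknown site {r.site_name!r}")
        cur_daily = current_capacity_daily(
            r.providers, params,
            task_shifting=p.task_shifting, task_sharing=p.task_sharing)
        opt_daily = optimum_capacity_daily(r.beds, params)
        if params.cap_current_at_beds:
            cur_daily = min(cur_daily, opt_daily)
        row: Dict = {
            "site_name": r.site_name,
            "month": r.month,
            "delivery_mode": p.delivery_mode,
            "fixed_site_group": group_key(p, "fixed_site_group"),
            "health_zone": p.health_zone,
            "province": p.province,
            "region": p.region or p.province,
            "performed": r.performed,
            "reached": r.reached,
            "seeking": r.seeking,
            "current_capacity_daily": cur_daily,
            "optimum_capacity_daily": opt_daily,
            "current_capacity": capacity_over_period(cur_daily,
                                                     r.days_of_operation),
            "optimum_capacity": capacity_over_period(opt_daily,
                                                     r.days_of_operation),
        }
        for col in ("target", "days_of_operation", "followup_48h",
                    "followup_7d", "followup_6w", "ae_mild", "ae_moderate",
                    "ae_severe", "sti_diagnosed", "sti_treated_circumcised",
                    "hiv_tests", "hiv_pos_referred"):
            row[col] = getattr(r, col)
        for col in _STOCK:
            row[col] = getattr(r, col)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(["site_name", "month"]).reset_index(drop=True)


def _period_columns(df: pd.DataFrame, granularity: str) -> pd.DataFrame:
    periods = [to_period(m, granularity) for m in df["month"]]
    df = df.copy()
    df["period"] = [p.label for p in periods]
    df["_period_sort"] = [(p.fiscal_year, p.index_within_year)
                          for p in periods]
    return df


def _opt_sum(s: pd.Series):
    """Sum treating all-absent as absent (None), partial data as partial sum."""
    vals = s.dropna()
    if vals.empty:
        return None
    return int(vals.sum())


def aggregate_records(profiles: Sequence[SiteProfile],
                      records: Sequence[MonthlyRecord],
                      level: str = "site",
                      granularity: str = "month",
                      params: Optional[CapacityParams] = None,
                      staffing_rule: str = "mean") -> pd.DataFrame:
    """Roll site-months up to (group, period) rows.

    Returns one row per (group, period) with summed additive fields,
    staffing/bed stocks per ``staffing_rule`` and recomputed capacities.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown aggregation level {level!r}")
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    if staffing_rule not in ("mean", "last"):
        raise ValueError("staffing_rule must be 'mean' or 'last'")

    df = records_frame(profiles, records, params)
    if df.empty:
        return pd.DataFrame(columns=["group", "period"] + _ADDITIVE + _STOCK)
    by_name = {p.site_name: p for p in profiles}
    df["group"] = [group_key(by_name[s], level) for s in df["site_name"]]
    df = _period_columns(df, granularity)

    out_rows: List[Dict] = []
    for (group, period, sort_key), sub in df.groupby(
            ["group", "period", "_period_sort"], sort=False):
        row: Dict = {"group": group, "period": period,
                     "_period_sort": sort_key}
        for col in _ADDITIVE:
            row[col] = _opt_sum(sub[col])
        # stocks: sum across sites within each month, then combine months
        monthly_totals = sub.groupby("month")[_STOCK].sum().sort_index()
        if staffing_rule == "mean":
            stock = monthly_totals.mean()
        else:
            stock = monthly_totals.iloc[-1]
        for col in _STOCK:
            row[col] = float(stock[col])
        row["n_sites"] = sub["site_name"].nunique()
        row["n_fixed_sites"] = sub.loc[
            sub["delivery_mode"] == "fixed", "site_name"].nunique()
        row["n_outreach_sites"] = sub.loc[
            sub["delivery_mode"] == "outreach", "site_name"].nunique()
        out_rows.append(row)

    out = pd.DataFrame(out_rows)
    out = out.sort_values(["_period_sort", "group"]).reset_index(drop=True)
    return out.drop(columns=["_period_sort"])


def aggregate_indicators(profiles: Sequence[SiteProfile],
                         records: Sequence[MonthlyRecord],
                         level: str = "site",
                         granularity: str = "month",
                         params: Optional[CapacityParams] = None,
                         staffing_rule: str = "mean") -> pd.DataFrame:
    """Indicator rows per (group, period), ratios as ratio-of-sums.

    U = sum(performed) / sum(current capacity) over the member site-months;
    a member with zero capacity and zero output contributes nothing and
    the aggregate is defined by the rest.
    """
    params = params or CapacityParams()
    agg = aggregate_records(profiles, records, level, granularity, params,
                            staffing_rule)
    rows: List[Dict] = []
    for _, r in agg.iterrows():
        staff_counts = {role: r[role] for role in
                        ("providers", "trained_assistants", "other_nurses",
                         "counselors", "mobilizers")}
        gaps = staffing_gap(r["beds"], staff_counts, params)
        ind = compute_indicator_set(
            performed=r["performed"],
            current_capacity=int(r["current_capacity"]),
            optimum_capacity=int(r["optimum_capacity"]),
            days_of_operation=int(r["days_of_operation"]),
            target=int(r["target"]) if r["target"] is not None else 0,
            staffing_gaps=gaps,
            cascade_counts=(r["reached"], r["seeking"]),
            followups=(r["followup_48h"], r["followup_7d"], r["followup_6w"]),
            adverse_events=(r["ae_mild"], r["ae_moderate"], r["ae_severe"]),
            hiv_tests=r["hiv_tests"],
        )
        row: Dict = {
            "group": r["group"],
            "period": r["period"],
            "performed": ind.performed,
            "target": r["target"],
            "current_capacity": ind.current_capacity,
            "optimum_capacity": ind.optimum_capacity,
            "utilization": ind.utilization.value,
            "utilization_display": ind.utilization.display,
            "utilization_class": ind.utilization.classification,
            "productivity": ind.productivity,
            "avg_daily_vmmcs": ind.avg_daily_vmmcs,
            "target_achievement": ind.target_achievement,
            "days_of_operation": r["days_of_operation"],
            "beds": r["beds"],
            "providers": r["providers"],
            "reached": ind.cascade.reached if ind.cascade else None,
            "seeking": ind.cascade.seeking if ind.cascade else None,
            "seeking_per_reached": (ind.cascade.seeking_per_reached
                                    if ind.cascade else None),
            "performed_per_seeking": (ind.cascade.performed_per_seeking
                                      if ind.cascade else None),
            "followup_rate_48h": ind.followup_rate_48h,
            "followup_rate_7d": ind.followup_rate_7d,
            "followup_rate_6w": ind.followup_rate_6w,
            "ae_rate_mild": ind.ae_rate_mild,
            "ae_rate_moderate": ind.ae_rate_moderate,
            "ae_rate_severe": ind.ae_rate_severe,
            "hiv_test_uptake": ind.hiv_test_uptake,
            "n_sites": r["n_sites"],
            "n_fixed_sites": r["n_fixed_sites"],
            "n_outreach_sites": r["n_outreach_sites"],
        }
        for role, gap in gaps.items():
            row[f"staff_gap_{role}"] = gap
        rows.append(row)
    return pd.DataFrame(rows)
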
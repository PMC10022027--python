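"""Visual-management outputs: indicator tables, figures and a dashboard.

Each figure is emitted as a (CSV, PNG) pair.  The CSV carries the exact
values from the aggregation/indicator modules — plots are views of those
tables, never recomputations — so every number a manager reads off a
chart can be traced to a row in its companion table.  Utilization charts
draw a reference line at 1 (balanced); productivity charts at 0.

The dashboard is a single self-contained HTML file: figures are embedded
as base64 PNGs and tables inlined, with no external resource references.
"""

from __future__ import annotations

import base64
import html
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from sitecap.aggregation import (
    GRANULARITIES,
    LEVELS,
    aggregate_indicators,
    aggregate_records,
)
from sitecap.data_model import CapacityParams, MonthlyRecord, SiteProfile

FIGURE_IDS: Tuple[str, ...] = (
    "vmmcs_over_time",
    "vmmcs_by_site",
    "site_counts",
    "target_vs_performed",
    "current_vs_optimum_capacity",
    "beds_vs_surgeons",
    "utilization",
    "productivity",
    "cascade",
)

_TITLES = {
    "vmmcs_over_time": "VMMCs performed over time by province",
    "vmmcs_by_site": "VMMCs performed by site group",
    "site_counts": "Fixed and outreach sites performing VMMCs",
    "target_vs_performed": "VMMC site targets vs VMMCs performed",
    "current_vs_optimum_capacity": "Current vs optimum VMMC site capacity",
    "beds_vs_surgeons": "Surgical beds and VMMC providers",
    "utilization": "Utilization rate (performed / current capacity)",
    "productivity": "Productivity gain/loss (performed - optimum capacity)",
    "cascade": "VMMC cascade: reached, seeking, performed",
}

_CLASS_COLORS = {"under-used": "#d95f02", "balanced": "#1b9e77",
                 "over-used": "#7570b3", "undefined": "#999999"}


@dataclass(frozen=True)
class ReportSpec:
    """What to render: which figures, at which level and granularity.

    ``date_range`` bounds are inclusive ISO "YYYY-MM" months (either may
    be None for unbounded).
    """

    figures: Tuple[str, ...] = FIGURE_IDS
    level: str = "fixed_site_group"
    granularity: str = "quarter"
    date_range: Tuple[Optional[str], Optional[str]] = (None, None)
    formats: Tuple[str, ...] = ("png",)

    def __post_init__(self):
        for f in self.figures:
            if f not in FIGURE_IDS:
                raise ValueError(f"unknown figure_id {f!r}; "
                                 f"choose from {FIGURE_IDS}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"unknown granularity {self.granularity!r}")
        start, end = self.date_range
        if start is not None and end is not None and start > end:
            raise ValueError(f"date_range start {start} after end {end}")


def _filter_range(records: Sequence[MonthlyRecord],
                  date_range) -> List[MonthlyRecord]:
    start, end = date_range
    out = []
    for r in records:
        if start is not None and r.month < start:
            continue
        if end is not None and r.month > end:
            continue
        out.append(r)
    return out


def _round_display(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding for output tables: ratios 2 dp, stocks 1 dp."""
    df = df.copy()
    ratio_cols = [c for c in df.columns if c in (
        "utilization", "utilization_display", "avg_daily_vmmcs",
        "target_achievement", "seeking_per_reached", "performed_per_seeking",
        "followup_rate_48h", "followup_rate_7d", "followup_rate_6w",
        "ae_rate_mild", "ae_rate_moderate", "ae_rate_severe",
        "hiv_test_uptake")]
    stock_cols = [c for c in df.columns if c in (
        "beds", "providers", "trained_assistants", "other_nurses",
        "mobilizers", "counselors") or c.startswith("staff_gap_")]
    for c in ratio_cols:
        df[c] = df[c].map(lambda v: None if pd.isna(v) else round(float(v), 2))
    for c in stock_cols:
        df[c] = df[c].map(lambda v: None if pd.isna(v) else round(float(v), 1))
    return df


# ---------------------------------------------------------------------------
# figure tables


def _figure_table(figure_id: str,
                  profiles: Sequence[SiteProfile],
                  records: Sequence[MonthlyRecord],
                  spec: "ReportSpec",
                  params: CapacityParams) -> pd.DataFrame:
    level = "province" if figure_id == "vmmcs_over_time" else spec.level
    if figure_id == "site_counts":
        agg = aggregate_records(profiles, records, level, spec.granularity,
                                params)
        return agg[["group", "period", "n_fixed_sites", "n_outreach_sites",
                    "n_sites"]]
    ind = aggregate_indicators(profiles, records, level, spec.granularity,
                               params)
    if ind.empty:
        return ind
    cols = {
        "vmmcs_over_time": ["group", "period", "performed"],
        "vmmcs_by_site": ["group", "period", "performed"],
        "target_vs_performed": ["group", "period", "target", "performed",
                                "target_achievement"],
        "current_vs_optimum_capacity": ["group", "period",
                                        "current_capacity",
                                        "optimum_capacity"],
        "beds_vs_surgeons": ["group", "period", "beds", "providers"],
        "utilization": ["group", "period", "performed", "current_capacity",
                        "utilization", "utilization_display",
                        "utilization_class"],
        "productivity": ["group", "period", "performed", "optimum_capacity",
                         "productivity"],
        "cascade": ["group", "period", "reached", "seeking", "performed",
                    "seeking_per_reached", "performed_per_seeking"],
    }[figure_id]
    return ind[cols]


def _plot_figure(figure_id: str, table: pd.DataFrame, out_path,
                 fmt: Optional[str] = None) -> None:
    fig, ax = plt.subplots(figsize=(9, 4.5))
    periods = list(dict.fromkeys(table["period"]))
    x = {p: i for i, p in enumerate(periods)}

    def lines(value_col, style="-"):
        for grp, sub in table.groupby("group", sort=True):
            xs = [x[p] for p in sub["period"]]
            ys = pd.to_numeric(sub[value_col], errors="coerce")
            ax.plot(xs, ys, style, marker="o", markersize=3, label=str(grp))

    if figure_id in ("vmmcs_over_time", "vmmcs_by_site"):
        lines("performed")
        ax.set_ylabel("VMMCs performed")
    elif figure_id == "site_counts":
        for col, style in (("n_fixed_sites", "-"), ("n_outreach_sites", "--")):
            totals = table.groupby("period", sort=False)[col].sum()
            ax.plot([x[p] for p in totals.index], totals.values, style,
                    marker="o", markersize=3,
                    label=col.replace("n_", "").replace("_", " "))
        ax.set_ylabel("number of sites")
    elif figure_id == "target_vs_performed":
        lines("target", "--")
        lines("performed", "-")
        ax.set_ylabel("VMMCs (dashed: target)")
    elif figure_id == "current_vs_optimum_capacity":
        lines("current_capacity", "-")
        lines("optimum_capacity", "--")
        ax.set_ylabel("VMMC capacity (dashed: optimum)")
    elif figure_id == "beds_vs_surgeons":
        lines("beds", "-")
        lines("providers", "--")
        ax.set_ylabel("beds (solid), providers (dashed)")
    elif figure_id == "utilization":
        for grp, sub in table.groupby("group", sort=True):
            xs = [x[p] for p in sub["period"]]
            ys = pd.to_numeric(sub["utilization"], errors="coerce")
            ax.plot(xs, ys, "-", color="#bbbbbb", zorder=1)
            colors = [_CLASS_COLORS.get(c, "#999999")
                      for c in sub["utilization_class"]]
            ax.scatter(xs, ys, c=colors, s=18, zorder=2, label=str(grp))
        ax.axhline(1.0, color="black", linewidth=1, linestyle=":")
        ax.set_ylabel("utilization rate")
    elif figure_id == "productivity":
        lines("productivity")
        ax.axhline(0.0, color="black", linewidth=1, linestyle=":")
        ax.set_ylabel("productivity gain/loss")
    elif figure_id == "cascade":
        for col, style in (("reached", "-"), ("seeking", "--"),
                           ("performed", ":")):
            totals = table.groupby("period", sort=False)[col].apply(
                lambda s: s.dropna().sum() if s.notna().any() else float("nan"))
            ax.plot([x[p] for p in totals.index], totals.values, style,
                    marker="o", markersize=3, label=col)
        ax.set_ylabel("people")

    ax.set_xticks(range(len(periods)))
    ax.set_xticklabels(periods, rotation=45, ha="right", fontsize=7)
    ax.set_title(_TITLES[figure_id], fontsize=10)
    if table["group"].nunique() <= 12 or figure_id == "cascade":
        ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100, format=fmt)
    plt.close(fig)


def build_report(profiles: Sequence[SiteProfile],
                 records: Sequence[MonthlyRecord],
                 spec: ReportSpec,
                 params: Optional[CapacityParams] = None,
                 out_dir="report") -> Dict[str, Dict[str, Path]]:
    """Render the requested figures as `<figure_id>.csv` + `<figure_id>.png`.

    Returns a mapping figure_id -> {"csv": path, "png": path}.  An empty
    selection (no records in the date range) writes an EMPTY_REPORT.txt
    notice and returns ``{}`` rather than crashing.
    """
    params = params or CapacityParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = _filter_range(records, spec.date_range)
    if not selected:
        notice = out_dir / "EMPTY_REPORT.txt"
        notice.write_text(
            "Empty report: no monthly records fall within the requested "
            f"date range {spec.date_range}.\n")
        return {}

    artifacts: Dict[str, Dict[str, Path]] = {}
    for fid in spec.figures:
        table = _figure_table(fid, profiles, selected, spec, params)
        table = _round_display(table)
        csv_path = out_dir / f"{fid}.csv"
        table.to_csv(csv_path, index=False)
        paths = {"csv": csv_path}
        for fmt in spec.formats:
            img_path = out_dir / f"{fid}.{fmt}"
            _plot_figure(fid, table, img_path)
            paths[fmt] = img_path
        artifacts[fid] = paths
    return artifacts


# ---------------------------------------------------------------------------
# dashboard

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8">
<title>VMMC site capacity &amp; productivity dashboard</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
section {{ margin-bottom: 3em; }}
table {{ border-collapse: collapse; font-size: 11px; }}
td, th {{ border: 1px solid #ccc; padding: 2px 6px; }}
.unavailable {{ color: #888; font-style: italic; }}
</style></head>
<body>
<h1>VMMC site capacity &amp; productivity dashboard</h1>
<p>Level: {level} | granularity: {granularity}</p>
{sections}
</body></html>
"""

_SECTION = """<section id="{fid}">
<h2>{title}</h2>
{body}
</section>
"""


def _table_html(df: pd.DataFrame, max_rows: int = 200) -> str:
    shown = df.head(max_rows)
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in shown.columns)
    rows = []
    for _, r in shown.iterrows():
        cells = "".join(
            "<td></td>" if pd.isna(v) else f"<td>{html.escape(str(v))}</td>"
            for v in r)
        rows.append(f"<tr>{cells}</tr>")
    more = (f"<p>... {len(df) - max_rows} more rows in the companion CSV</p>"
            if len(df) > max_rows else "")
    return (f"<table><thead><tr>{head}</tr></thead>"
            f"<tbody>{''.join(rows)}</tbody></table>{more}")


def dashboard(profiles: Sequence[SiteProfile],
              records: Sequence[MonthlyRecord],
              params: Optional[CapacityParams] = None,
              out_path="dashboard.html",
              level: str = "fixed_site_group",
              granularity: str = "quarter") -> Path:
    """Write a single self-contained HTML dashboard with all nine figures.

    Deterministic given the dataset and parameters; a figure whose inputs
    are entirely unreported (e.g. no cascade counts anywhere) renders a
    "data unavailable" notice instead of an empty chart.
    """
    params = params or CapacityParams()
    out_path = Path(out_path)
    spec = ReportSpec(level=level, granularity=granularity)
    sections = []
    for fid in FIGURE_IDS:
        title = html.escape(_TITLES[fid])
        if not records:
            body = '<p class="unavailable">data unavailable</p>'
            sections.append(_SECTION.format(fid=fid, title=title, body=body))
            continue
        table = _round_display(
            _figure_table(fid, profiles, records, spec, params))
        if fid == "cascade":
            # performed alone is no cascade: demand data must exist
            value_cols = ["reached", "seeking"]
        else:
            value_cols = [c for c in table.columns if c not in
                          ("group", "period", "utilization_class")]
        if table.empty or table[value_cols].isna().all().all():
            body = '<p class="unavailable">data unavailable</p>'
        else:
            buf = io.BytesIO()
            _plot_figure(fid, table, buf, fmt="png")
            b64 = base64.b64encode(buf.getvalue()).decode("ascii")
            body = (f'<img alt="{title}" '
                    f'src="data:image/png;base64,{b64}">\n'
                    + _table_html(table))
        sections.append(_SECTION.format(fid=fid, title=title, body=body))
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(_PAGE.format(level=html.escape(level),
                                     granularity=html.escape(granularity),
                                     sections="\n".join(sections)),
                        encoding="utf-8")
    return out_path
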
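"""Cohort-level summary report: the headline counts and percentages.

Collects, from a validated cohort, the quantities a trajectory-classification
analysis reports: the initial-period prevalence of each change category, the
fraction with progressive ILD (moderate or significant decline) over the
initial 12 months, the long-term (>= 3 FVC measurements) subset fraction,
the overall-course distribution, the fraction with no decline episode, the
pattern split among overall decliners, and all-cause mortality.  All
percentages are integers rounded half away from zero, as in printed tables.
"""

from __future__ import annotations

import pandas as pd

from .classify import (
    OVERALL_CATEGORY_ORDER,
    PERIOD_CATEGORY_ORDER,
    OverallCategory,
    PatternLabel,
    PeriodCategory,
    Thresholds,
    DEFAULT_THRESHOLDS,
    patient_summary,
    round_half_up,
)
from .cohort import Cohort

_DECLINE_OVERALL = {
    OverallCategory.MAJOR_DECLINE.value,
    OverallCategory.SIGNIFICANT_DECLINE.value,
    OverallCategory.MODERATE_DECLINE.value,
}


def _pct(numerator: int, denominator: int):
    return round_half_up(100.0 * numerator / denominator) if denominator else None


def headline_report(
    cohort: Cohort, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> dict:
    """Compute every headline count/percentage pair from scratch."""
    summary = patient_summary(cohort, thresholds)
    n_total = len(summary)

    out: dict = {"n_total": n_total, "thresholds": thresholds.to_dict()}

    # Initial 12-month period prevalence, over patients with a period k=1.
    initial = summary[summary["first_period_category"].notna()]
    n_initial = len(initial)
    out["n_initial_period"] = n_initial
    counts = initial["first_period_category"].value_counts()
    for cat in PERIOD_CATEGORY_ORDER:
        n = int(counts.get(cat.value, 0))
        out[f"initial_{cat.value}_n"] = n
        out[f"initial_{cat.value}_pct"] = _pct(n, n_initial)
    n_prog = int(
        counts.get(PeriodCategory.SIGNIFICANT_DECLINE.value, 0)
        + counts.get(PeriodCategory.MODERATE_DECLINE.value, 0)
    )
    out["initial_progressive_n"] = n_prog
    out["initial_progressive_pct"] = _pct(n_prog, n_initial)

    # Long-term subset: >= 3 usable FVC measurements.
    long_term = summary[summary["n_fvc"] >= 3]
    out["long_term_n"] = len(long_term)
    out["long_term_pct"] = _pct(len(long_term), n_total)

    # Overall course and episode history over the long-term analysis subset
    # (>= 2 computable periods).
    analysed = long_term[long_term["n_periods"] >= 2]
    n_analysed = len(analysed)
    out["n_long_term_analysed"] = n_analysed
    overall_counts = analysed["overall_category"].value_counts()
    for cat in OVERALL_CATEGORY_ORDER:
        n = int(overall_counts.get(cat.value, 0))
        out[f"overall_{cat.value}_n"] = n
        out[f"overall_{cat.value}_pct"] = _pct(n, n_analysed)

    no_decline = int((analysed["episode_column"] == "no_decline").sum())
    out["no_decline_n"] = no_decline
    out["no_decline_pct"] = _pct(no_decline, n_analysed)

    # Pattern split among patients with an overall decline.
    decliners = analysed[analysed["overall_category"].isin(_DECLINE_OVERALL)]
    n_decliners = len(decliners)
    out["overall_decliners_n"] = n_decliners
    pattern_counts = decliners["pattern"].value_counts()
    for label in (PatternLabel.RAPID, PatternLabel.PROGRESSIVE, PatternLabel.SLOW):
        n = int(pattern_counts.get(label.value, 0))
        out[f"pattern_{label.value}_n"] = n
        out[f"pattern_{label.value}_pct"] = _pct(n, n_decliners)

    # All-cause mortality.
    deaths = int(summary["died"].sum())
    out["deaths_n"] = deaths
    out["deaths_pct"] = _pct(deaths, n_total)
    return out


def report_markdown(report: dict) -> str:
    """Render the headline report as a small Markdown document."""
    lines = [
        "# Cohort trajectory report",
        "",
        f"Patients: {report['n_total']}  "
        f"(initial-period classifiable: {report['n_initial_period']})",
        "",
        "## Initial 12-month period",
        "",
        "| category | n | % |",
        "|---|---|---|",
    ]
    for cat in PERIOD_CATEGORY_ORDER:
        lines.append(
            f"| {cat.value} | {report[f'initial_{cat.value}_n']} "
            f"| {report[f'initial_{cat.value}_pct']} |"
        )
    lines += [
        f"| progressive (moderate+significant) | {report['initial_progressive_n']} "
        f"| {report['initial_progressive_pct']} |",
        "",
        "## Long-term course",
        "",
        f"Patients with >= 3 FVC measurements: {report['long_term_n']} "
        f"({report['long_term_pct']}%); analysed (>= 2 periods): "
        f"{report['n_long_term_analysed']}",
        "",
        "| overall course | n | % |",
        "|---|---|---|",
    ]
    for cat in OVERALL_CATEGORY_ORDER:
        lines.append(
            f"| {cat.value} | {report[f'overall_{cat.value}_n']} "
            f"| {report[f'overall_{cat.value}_pct']} |"
        )
    lines += [
        "",
        f"No decline episode: {report['no_decline_n']} ({report['no_decline_pct']}%)",
        "",
        "## Pattern among overall decliners "
        f"(n={report['overall_decliners_n']})",
        "",
        "| pattern | n | % |",
        "|---|---|---|",
        f"| rapid | {report['pattern_rapid_n']} | {report['pattern_rapid_pct']} |",
        f"| progressive | {report['pattern_progressive_n']} "
        f"| {report['pattern_progressive_pct']} |",
        f"| slow | {report['pattern_slow_n']} | {report['pattern_slow_pct']} |",
        "",
        "## Mortality",
        "",
        f"Deaths: {report['deaths_n']} / {report['n_total']} "
        f"({report['deaths_pct']}%)",
        "",
    ]
    return "\n".join(lines)


def report_frame(report: dict) -> pd.DataFrame:
    """Flat key/value view of the report for CSV output."""
    rows = [
        {"metric": k, "value": v}
        for k, v in report.items()
        if k != "thresholds"
    ]
    return pd.DataFrame(rows)
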
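"""Threshold classifiers and derived taxonomies for FVC/DLCO trajectories.

All changes are absolute differences in %-predicted points.  Three taxonomies
are derived from classified 12-month periods:

* per-period category — significant decline (< -10), moderate decline
  ([-10, -5]), stable ((-5, 5)), improvement (>= +5);
* overall course — the same bins applied to last-minus-first FVC, with an
  extra *major decline* bin below -20 (significant then covers [-20, -10));
* decline-episode column — how many moderate/significant decline periods a
  patient accumulated, as a six-way partition of the (n_moderate,
  n_significant) count pair;
* progression pattern — rapid (declines only, at least two), progressive
  (declines >= stable/improving periods), slow (fewer declines than
  stable/improving periods), non-declining (no decline period at all).

A tie between decline and stable counts is labelled progressive: a patient
with as many declining as stable periods is not "more stable than declining",
and flagging progression is the clinically conservative choice.  A single
decline period with no other periods is progressive, not rapid — rapid is
reserved for repeated, uninterrupted decline.

Bin edges are configurable through :class:`Thresholds`; the defaults are the
conventional SSc-ILD progression criteria.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
import yaml

from .cohort import Cohort, PatientRecord
from .errors import DomainError
from .periods import Period, build_periods, count_usable_fvc_measurements


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (as printed tables do)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


class PeriodCategory(enum.Enum):
    SIGNIFICANT_DECLINE = "significant_decline"
    MODERATE_DECLINE = "moderate_decline"
    STABLE = "stable"
    IMPROVEMENT = "improvement"


class OverallCategory(enum.Enum):
    MAJOR_DECLINE = "major_decline"
    SIGNIFICANT_DECLINE = "significant_decline"
    MODERATE_DECLINE = "moderate_decline"
    STABLE = "stable"
    IMPROVEMENT = "improvement"


class EpisodeColumn(enum.Enum):
    NO_DECLINE = "no_decline"
    ONE_MODERATE = "one_moderate"
    ONE_SIGNIFICANT = "one_significant"
    MULTI_ONLY_MODERATE = "multi_only_moderate"
    MIXED_SIG_AND_MOD = "mixed_sig_and_mod"
    MULTI_ONLY_SIGNIFICANT = "multi_only_significant"


class PatternLabel(enum.Enum):
    RAPID = "rapid"
    PROGRESSIVE = "progressive"
    SLOW = "slow"
    NON_DECLINING = "non_declining"


PERIOD_CATEGORY_ORDER = [
    PeriodCategory.SIGNIFICANT_DECLINE,
    PeriodCategory.MODERATE_DECLINE,
    PeriodCategory.STABLE,
    PeriodCategory.IMPROVEMENT,
]
OVERALL_CATEGORY_ORDER = [
    OverallCategory.MAJOR_DECLINE,
    OverallCategory.SIGNIFICANT_DECLINE,
    OverallCategory.MODERATE_DECLINE,
    OverallCategory.STABLE,
    OverallCategory.IMPROVEMENT,
]
EPISODE_COLUMN_ORDER = [
    EpisodeColumn.NO_DECLINE,
    EpisodeColumn.ONE_MODERATE,
    EpisodeColumn.ONE_SIGNIFICANT,
    EpisodeColumn.MULTI_ONLY_MODERATE,
    EpisodeColumn.MIXED_SIG_AND_MOD,
    EpisodeColumn.MULTI_ONLY_SIGNIFICANT,
]

DECLINE_CATEGORIES = {PeriodCategory.SIGNIFICANT_DECLINE, PeriodCategory.MODERATE_DECLINE}


@dataclass(frozen=True)
class Thresholds:
    """All classification bin edges, in %-predicted points.

    ``period_significant``/``period_moderate``/``period_improvement`` bound
    the per-period bins: significant iff delta < period_significant, moderate
    iff period_significant <= delta <= period_moderate, improvement iff
    delta >= period_improvement.  ``overall_major`` adds the major-decline
    bin for the first-to-last course.  The combined fibrosis endpoint fires
    when delta FVC <= combined_fvc_major, or when combined_fvc_major <
    delta FVC <= combined_fvc_minor together with delta DLCO <=
    combined_dlco.  The FVC-only significant bin is strict (< -10) while the
    combined endpoint's FVC arm is inclusive (<= -10): both follow the usual
    published wording and both are configurable here.
    """

    period_significant: float = -10.0
    period_moderate: float = -5.0
    period_improvement: float = 5.0
    overall_major: float = -20.0
    combined_fvc_major: float = -10.0
    combined_fvc_minor: float = -5.0
    combined_dlco: float = -15.0
    interval_months: float = 12.0
    tolerance_months: float = 3.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Thresholds":
        data = yaml.safe_load(text) or {}
        return cls(**data)


DEFAULT_THRESHOLDS = Thresholds()


def classify_period_delta(
    delta_fvc: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> PeriodCategory:
    """Four-way per-period classification of an absolute FVC change."""
    if delta_fvc is None or not math.isfinite(delta_fvc):
        raise DomainError(f"delta_fvc must be finite, got {delta_fvc!r}")
    if delta_fvc < thresholds.period_significant:
        return PeriodCategory.SIGNIFICANT_DECLINE
    if delta_fvc <= thresholds.period_moderate:
        return PeriodCategory.MODERATE_DECLINE
    if delta_fvc < thresholds.period_improvement:
        return PeriodCategory.STABLE
    return PeriodCategory.IMPROVEMENT


class CombinedResult(NamedTuple):
    """Outcome of the combined FVC+DLCO progressive-fibrosis endpoint."""

    progressive: bool
    dlco_missing: bool

    def __bool__(self) -> bool:  # allows `if is_progressive_combined(...)`
        return self.progressive


def is_progressive_combined(
    delta_fvc: float,
    delta_dlco: Optional[float],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CombinedResult:
    """Combined endpoint: FVC fall >= 10 points, or FVC fall of 5-10 points
    together with a DLCO fall >= 15 points.

    A missing DLCO change with an FVC fall in the 5-10 band cannot satisfy
    the DLCO arm; the result is then non-progressive with ``dlco_missing``
    set, so callers can count indeterminate cases.
    """
    if delta_fvc is None or not math.isfinite(delta_fvc):
        raise DomainError(f"delta_fvc must be finite, got {delta_fvc!r}")
    if delta_fvc <= thresholds.combined_fvc_major:
        return CombinedResult(True, False)
    if delta_fvc <= thresholds.combined_fvc_minor:
        if delta_dlco is None:
            return CombinedResult(False, True)
        return CombinedResult(delta_dlco <= thresholds.combined_dlco, False)
    return CombinedResult(False, False)


def classify_overall_course(
    fvc_first: float, fvc_last: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> OverallCategory:
    """Five-way classification of the first-to-last FVC change."""
    d = fvc_last - fvc_first
    if not math.isfinite(d):
        raise DomainError(f"overall delta must be finite, got {d!r}")
    if d < thresholds.overall_major:
        return OverallCategory.MAJOR_DECLINE
    if d < thresholds.period_significant:
        return OverallCategory.SIGNIFICANT_DECLINE
    if d <= thresholds.period_moderate:
        return OverallCategory.MODERATE_DECLINE
    if d < thresholds.period_improvement:
        return OverallCategory.STABLE
    return OverallCategory.IMPROVEMENT


def _decline_counts(categories: Sequence[PeriodCategory]) -> tuple[int, int]:
    m = sum(1 for c in categories if c is PeriodCategory.MODERATE_DECLINE)
    s = sum(1 for c in categories if c is PeriodCategory.SIGNIFICANT_DECLINE)
    return m, s


def assign_episode_column(categories: Sequence[PeriodCategory]) -> EpisodeColumn:
    """Partition a patient's decline-episode history into the six-way column.

    Depends only on the multiset of categories, never their order.
    """
    if len(categories) == 0:
        raise DomainError("cannot assign an episode column to an empty period list")
    m, s = _decline_counts(categories)
    if m == 0 and s == 0:
        return EpisodeColumn.NO_DECLINE
    if m == 1 and s == 0:
        return EpisodeColumn.ONE_MODERATE
    if m == 0 and s == 1:
        return EpisodeColumn.ONE_SIGNIFICANT
    if s == 0:
        return EpisodeColumn.MULTI_ONLY_MODERATE
    if m == 0:
        return EpisodeColumn.MULTI_ONLY_SIGNIFICANT
    return EpisodeColumn.MIXED_SIG_AND_MOD


def classify_pattern(categories: Sequence[PeriodCategory]) -> PatternLabel:
    """Progression-pattern label over a patient's classified periods."""
    if len(categories) < 2:
        raise DomainError("pattern classification needs at least two periods")
    m, s = _decline_counts(categories)
    declines = m + s
    stable = len(categories) - declines
    if declines == 0:
        return PatternLabel.NON_DECLINING
    if stable == 0 and declines >= 2:
        return PatternLabel.RAPID
    if declines >= stable:
        return PatternLabel.PROGRESSIVE
    return PatternLabel.SLOW


# ---------------------------------------------------------------------------
# Cohort-level aggregations
# ---------------------------------------------------------------------------


def classify_periods(
    periods: Iterable[Period], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[Period]:
    """Attach a PeriodCategory to each period in place; returns the list."""
    out = list(periods)
    for p in out:
        p.category = classify_period_delta(p.delta_fvc, thresholds)
    return out


def cohort_periods(
    cohort: Cohort, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> dict[str, list[Period]]:
    """Build and classify periods for every patient in the cohort."""
    return {
        p.patient_id: classify_periods(
            build_periods(p, thresholds.interval_months, thresholds.tolerance_months),
            thresholds,
        )
        for p in cohort
    }


def periods_frame(periods_by_patient: dict[str, list[Period]]) -> pd.DataFrame:
    """Long-format classified-period table (one row per patient-period)."""
    rows = []
    for pid, periods in periods_by_patient.items():
        for p in periods:
            combined = is_progressive_combined(p.delta_fvc, p.delta_dlco)
            rows.append(
                {
                    "patient_id": pid,
                    "index_k": p.index_k,
                    "start_t": p.start_t,
                    "end_t": p.end_t,
                    "delta_fvc": p.delta_fvc,
                    "delta_dlco": p.delta_dlco,
                    "category": p.category.value,
                    "combined_progressive": combined.progressive,
                    "dlco_missing_flag": combined.dlco_missing,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "index_k",
            "start_t",
            "end_t",
            "delta_fvc",
            "delta_dlco",
            "category",
            "combined_progressive",
            "dlco_missing_flag",
        ],
    )


def period_prevalence(periods_by_patient: dict[str, list[Period]]) -> pd.DataFrame:
    """Per-period-index category proportions (rows sum to 1).

    For each anniversary index k, the fraction of patients contributing a
    period k that falls in each category.
    """
    counts: dict[int, dict[PeriodCategory, int]] = {}
    for periods in periods_by_patient.values():
        for p in periods:
            counts.setdefault(p.index_k, {c: 0 for c in PERIOD_CATEGORY_ORDER})
            counts[p.index_k][p.category] += 1
    rows = []
    for k in sorted(counts):
        total = sum(counts[k].values())
        row = {"index_k": k, "n": total}
        for c in PERIOD_CATEGORY_ORDER:
            row[c.value] = counts[k][c] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=["index_k", "n"] + [c.value for c in PERIOD_CATEGORY_ORDER])


def transition_counts(periods_by_patient: dict[str, list[Period]]) -> pd.DataFrame:
    """4x4 matrix of category transitions over consecutive (k, k+1) pairs.

    Only pairs where a patient has both period k and period k+1 contribute;
    the grand total equals the number of such pairs in the cohort.
    """
    labels = [c.value for c in PERIOD_CATEGORY_ORDER]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for periods in periods_by_patient.values():
        by_k = {p.index_k: p for p in periods}
        for k, p in by_k.items():
            nxt = by_k.get(k + 1)
            if nxt is not None:
                mat.loc[p.category.value, nxt.category.value] += 1
    mat.index.name = "from"
    mat.columns.name = "to"
    return mat


def patient_summary(
    cohort: Cohort, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Per-patient derived labels over the full follow-up.

    Columns: number of usable FVC measurements, number of periods, the
    first-period category, overall course (first to last available FVC),
    episode column and pattern (both only for patients with >= 2 periods),
    the combined-endpoint flag for the initial period, and vital status.
    """
    by_patient = cohort_periods(cohort, thresholds)
    rows = []
    for patient in cohort:
        periods = by_patient[patient.patient_id]
        cats = [p.category for p in periods]
        fvc_values = [v.fvc_pct_pred for v in patient.visits if v.fvc_pct_pred is not None]
        overall = (
            classify_overall_course(fvc_values[0], fvc_values[-1], thresholds)
            if len(fvc_values) >= 2
            else None
        )
        first = next((p for p in periods if p.index_k == 1), None)
        combined = (
            is_progressive_combined(first.delta_fvc, first.delta_dlco, thresholds)
            if first is not None
            else None
        )
        rows.append(
            {
                "patient_id": patient.patient_id,
                "n_fvc": count_usable_fvc_measurements(patient),
                "n_periods": len(periods),
                "first_period_category": first.category.value if first else None,
                "initial_combined_progressive": combined.progressive if combined else None,
                "initial_dlco_missing": combined.dlco_missing if combined else None,
                "overall_category": overall.value if overall else None,
                "episode_column": (
                    assign_episode_column(cats).value if len(cats) >= 1 else None
                ),
                "pattern": classify_pattern(cats).value if len(cats) >= 2 else None,
                "died": patient.died,
            }
        )
    return pd.DataFrame(rows)


def crosstab_overall_by_episode(
    cohort: Cohort, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table of overall course by decline-episode column.

    The analysed subset is the long-term population: patients with at least
    three usable FVC measurements and at least two computable periods.
    Returns (counts, column_percentages); percentages are computed within
    each column and rounded half away from zero.  Structural zeros are
    reported as 0, not suppressed.
    """
    summary = patient_summary(cohort, thresholds)
    subset = summary[(summary["n_fvc"] >= 3) & (summary["n_periods"] >= 2)]
    row_labels = [c.value for c in OVERALL_CATEGORY_ORDER]
    col_labels = [c.value for c in EPISODE_COLUMN_ORDER]
    counts = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=int)
    for _, row in subset.iterrows():
        counts.loc[row["overall_category"], row["episode_column"]] += 1
    col_totals = counts.sum(axis=0)
    pct = counts.copy().astype(float)
    for col in col_labels:
        total = col_totals[col]
        pct[col] = [
            round_half_up(100.0 * c / total) if total else float("nan") for c in counts[col]
        ]
    counts.index.name = pct.index.name = "overall_category"
    return counts, pct


def mortality_summary(
    cohort: Cohort, grouping: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Deaths per group: n, deaths and a rounded percentage.

    ``grouping`` maps patient_id -> group label; patients without a label are
    grouped under "ungrouped".  With no grouping, a single "all" row is
    returned.  An empty group yields n=0 with a blank percentage; no
    inferential statistics are computed.
    """
    groups: dict[str, list[PatientRecord]] = {}
    for patient in cohort:
        label = "all" if grouping is None else grouping.get(patient.patient_id, "ungrouped")
        groups.setdefault(label, []).append(patient)
    rows = []
    for label in sorted(groups):
        members = groups[label]
        n = len(members)
        deaths = sum(1 for p in members if p.died)
        rows.append(
            {
                "group": label,
                "n": n,
                "deaths": deaths,
                "pct": round_half_up(100.0 * deaths / n) if n else None,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "deaths", "pct"])
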
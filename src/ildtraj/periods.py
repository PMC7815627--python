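"""Anchoring of 12-month observation periods onto irregular visit series.

Registry patients are not seen on exact anniversaries.  Each period k is
anchored to the baseline-fixed anniversary a_k = k * interval (12 months by
default) and ends at the FVC-bearing visit closest to a_k within ±tolerance
(3 months).  A period's start is the previous period's end when one exists,
so consecutive periods share endpoints; an isolated period whose k-1
anniversary has no matched visit is not emitted (except k=1, which may start
at baseline).  Periods therefore need not be consecutive, and a visit serves
as the end of at most one period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .cohort import PatientRecord, Visit


@dataclass
class Period:
    """One anchored observation window with its lung-function changes.

    ``delta_fvc``/``delta_dlco`` are absolute differences in %-predicted
    points (end minus start).  ``category`` is filled in by the
    classification layer.
    """

    patient_id: str
    index_k: int
    start_t: float
    end_t: float
    start_fvc: float
    end_fvc: float
    start_dlco: Optional[float] = None
    end_dlco: Optional[float] = None
    category: Optional[object] = None

    @property
    def delta_fvc(self) -> float:
        return self.end_fvc - self.start_fvc

    @property
    def delta_dlco(self) -> Optional[float]:
        if self.start_dlco is None or self.end_dlco is None:
            return None
        return self.end_dlco - self.start_dlco

    @property
    def dlco_missing(self) -> bool:
        return self.delta_dlco is None


def _match_anniversary(
    visits: list[Visit], anniversary: float, tolerance: float
) -> Optional[Visit]:
    """FVC-bearing visit inside [a-tol, a+tol] closest to a; ties -> earlier."""
    candidates = [
        v
        for v in visits
        if v.fvc_pct_pred is not None and abs(v.t_months - anniversary) <= tolerance
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda v: (abs(v.t_months - anniversary), v.t_months))


def build_periods(
    patient: PatientRecord,
    interval_months: float = 12.0,
    tolerance_months: float = 3.0,
) -> list[Period]:
    """Emit the anchored periods computable from a patient's visit series.

    Visits with missing FVC are invisible to matching.  A period k is emitted
    only when both its end (anniversary-k match) and its start (anniversary
    k-1 match, or baseline for k=1) exist.
    """
    visits = [v for v in patient.visits if v.fvc_pct_pred is not None]
    if not visits or visits[0].t_months != 0:
        return []
    baseline = visits[0]
    max_t = visits[-1].t_months
    k_max = int(math.floor(max_t / interval_months)) + 1

    matched: dict[int, Visit] = {0: baseline}
    for k in range(1, k_max + 1):
        hit = _match_anniversary(visits, k * interval_months, tolerance_months)
        if hit is not None:
            matched[k] = hit

    periods: list[Period] = []
    for k in range(1, k_max + 1):
        end = matched.get(k)
        start = matched.get(k - 1)
        if end is None or start is None or end.t_months <= start.t_months:
            continue
        periods.append(
            Period(
                patient_id=patient.patient_id,
                index_k=k,
                start_t=start.t_months,
                end_t=end.t_months,
                start_fvc=start.fvc_pct_pred,
                end_fvc=end.fvc_pct_pred,
                start_dlco=start.dlco_pct_pred,
                end_dlco=end.dlco_pct_pred,
            )
        )
    return periods


def count_usable_fvc_measurements(patient: PatientRecord) -> int:
    """Number of visits with a non-missing FVC value."""
    return patient.n_fvc_measurements()
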
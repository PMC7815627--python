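"""Domain types and long-format CSV I/O for registry lung-function cohorts.

A cohort is stored as two CSV files:

* a *visits* file — one row per pulmonary-function test, long format:
  ``patient_id, t_months, fvc_pct_pred, dlco_pct_pred`` (empty cell = missing);
* a *patients* file — one row per patient with baseline covariates and
  vital status; boolean columns are coded 0/1.

Time is expressed in months since each patient's baseline visit.  If a
calendar-date column is supplied instead of ``t_months`` it must be converted
upstream using 1 month = 365.25/12 days; this module only deals in months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import IntegrityError, SchemaError

DAYS_PER_MONTH = 365.25 / 12.0

VISIT_COLUMNS = ["patient_id", "t_months", "fvc_pct_pred", "dlco_pct_pred"]
PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "disease_duration_years",
    "subtype",
    "ata",
    "aca",
    "ara",
    "mrss",
    "reflux_dysphagia",
    "esr",
    "crp_elevated",
    "nyha_class",
    "immunosuppressant_use",
    "died",
]

_OPTIONAL_PATIENT_COLUMNS = {"immunosuppressant_use"}


@dataclass(frozen=True)
class Visit:
    """One timestamped lung-function measurement.

    FVC and DLCO are stored as percent of the predicted value for a reference
    individual of the same sex, age and height.  Either measurement may be
    missing (``None``); when present, FVC must lie in the open interval
    (0, 200) %-predicted.
    """

    patient_id: str
    t_months: float
    fvc_pct_pred: Optional[float] = None
    dlco_pct_pred: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_months) or self.t_months < 0:
            raise SchemaError(
                f"visit ({self.patient_id!r}, t={self.t_months}): t_months must be finite and >= 0"
            )
        if self.fvc_pct_pred is not None and not 0 < self.fvc_pct_pred < 200:
            raise SchemaError(
                f"visit ({self.patient_id!r}, t={self.t_months}): "
                f"fvc_pct_pred={self.fvc_pct_pred} outside (0, 200)"
            )
        if self.dlco_pct_pred is not None and not 0 < self.dlco_pct_pred < 200:
            raise SchemaError(
                f"visit ({self.patient_id!r}, t={self.t_months}): "
                f"dlco_pct_pred={self.dlco_pct_pred} outside (0, 200)"
            )


@dataclass
class PatientRecord:
    """Baseline covariates, visit series and vital status for one patient."""

    patient_id: str
    age_years: float
    sex: str  # "male" | "female"
    disease_duration_years: float
    subtype: str  # "diffuse" | "limited"
    ata: bool
    aca: bool
    ara: bool
    mrss: int
    reflux_dysphagia: bool
    esr: float
    crp_elevated: bool
    nyha_class: int
    immunosuppressant_use: Optional[bool]
    died: bool
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise SchemaError(f"patient {self.patient_id!r}: sex must be male/female, got {self.sex!r}")
        if self.subtype not in ("diffuse", "limited"):
            raise SchemaError(
                f"patient {self.patient_id!r}: subtype must be diffuse/limited, got {self.subtype!r}"
            )
        if not 0 <= self.mrss <= 51:
            raise SchemaError(f"patient {self.patient_id!r}: mrss={self.mrss} outside [0, 51]")
        if self.nyha_class not in (1, 2, 3, 4):
            raise SchemaError(f"patient {self.patient_id!r}: nyha_class={self.nyha_class} not in 1..4")
        self.visits = sorted(self.visits, key=lambda v: v.t_months)
        times = [v.t_months for v in self.visits]
        if len(set(times)) != len(times):
            dup = next(t for i, t in enumerate(times) if t in times[:i])
            raise IntegrityError(f"patient {self.patient_id!r}: duplicate visit at t_months={dup}")
        if self.visits and self.visits[0].t_months != 0:
            raise SchemaError(
                f"patient {self.patient_id!r}: first visit must be at t_months=0 (baseline), "
                f"got {self.visits[0].t_months}"
            )

    @property
    def baseline(self) -> Optional[Visit]:
        return self.visits[0] if self.visits else None

    def n_fvc_measurements(self) -> int:
        return sum(1 for v in self.visits if v.fvc_pct_pred is not None)


@dataclass
class Cohort:
    """A validated set of patients with unique identifiers."""

    patients: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = next(i for k, i in enumerate(ids) if i in ids[:k])
            raise IntegrityError(f"duplicate patient_id {dup!r}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def subset(self, ids: Iterable[str], provenance: str = "") -> "Cohort":
        keep = set(ids)
        return Cohort(
            patients=[p for p in self.patients if p.patient_id in keep],
            provenance=provenance or self.provenance,
        )


@dataclass
class ExclusionLog:
    """One reason code per excluded patient, in input order."""

    entries: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, reason_code)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["patient_id", "reason_code"])

    def __len__(self) -> int:
        return len(self.entries)


def _as_bool(value, column: str, patient_id: str) -> bool:
    if pd.isna(value):
        raise SchemaError(f"patient {patient_id!r}: missing value in boolean column {column!r}")
    if value in (0, 1, "0", "1", True, False):
        return bool(int(value))
    raise SchemaError(f"patient {patient_id!r}: column {column!r} must be 0/1, got {value!r}")


def read_cohort(visits_path, patients_path, provenance: str = "") -> Cohort:
    """Read and validate a cohort from the two-file CSV schema.

    Raises :class:`SchemaError` naming the first missing mandatory column and
    :class:`IntegrityError` on duplicate (patient_id, t_months) rows.
    """
    visits_df = pd.read_csv(visits_path, dtype={"patient_id": str})
    patients_df = pd.read_csv(patients_path, dtype={"patient_id": str})

    for col in VISIT_COLUMNS:
        if col not in visits_df.columns:
            raise SchemaError(f"visits file is missing mandatory column {col!r}")
    for col in PATIENT_COLUMNS:
        if col in _OPTIONAL_PATIENT_COLUMNS:
            continue
        if col not in patients_df.columns:
            raise SchemaError(f"patients file is missing mandatory column {col!r}")
    if "immunosuppressant_use" not in patients_df.columns:
        patients_df["immunosuppressant_use"] = float("nan")

    dup_mask = visits_df.duplicated(subset=["patient_id", "t_months"], keep=False)
    if dup_mask.any():
        row = visits_df[dup_mask].iloc[0]
        raise IntegrityError(
            f"duplicate visit row for (patient_id={row['patient_id']!r}, t_months={row['t_months']})"
        )

    visits_by_patient: dict[str, list[Visit]] = {}
    for row in visits_df.itertuples(index=False):
        visits_by_patient.setdefault(row.patient_id, []).append(
            Visit(
                patient_id=row.patient_id,
                t_months=float(row.t_months),
                fvc_pct_pred=None if pd.isna(row.fvc_pct_pred) else float(row.fvc_pct_pred),
                dlco_pct_pred=None if pd.isna(row.dlco_pct_pred) else float(row.dlco_pct_pred),
            )
        )

    known_ids = set(patients_df["patient_id"])
    orphans = set(visits_by_patient) - known_ids
    if orphans:
        raise IntegrityError(f"visits reference unknown patient_id(s): {sorted(orphans)[:5]}")

    patients = []
    for row in patients_df.itertuples(index=False):
        pid = row.patient_id
        immuno = row.immunosuppressant_use
        patients.append(
            PatientRecord(
                patient_id=pid,
                age_years=float(row.age_years),
                sex=str(row.sex),
                disease_duration_years=float(row.disease_duration_years),
                subtype=str(row.subtype),
                ata=_as_bool(row.ata, "ata", pid),
                aca=_as_bool(row.aca, "aca", pid),
                ara=_as_bool(row.ara, "ara", pid),
                mrss=int(row.mrss),
                reflux_dysphagia=_as_bool(row.reflux_dysphagia, "reflux_dysphagia", pid),
                esr=float(row.esr),
                crp_elevated=_as_bool(row.crp_elevated, "crp_elevated", pid),
                nyha_class=int(row.nyha_class),
                immunosuppressant_use=None if pd.isna(immuno) else bool(int(immuno)),
                died=_as_bool(row.died, "died", pid),
                visits=visits_by_patient.get(pid, []),
            )
        )
    return Cohort(patients=patients, provenance=provenance)


def write_cohort(cohort: Cohort, visits_path, patients_path) -> None:
    """Write a cohort back to the two-file CSV schema (inverse of read_cohort).

    Column order is stable; booleans are written as 0/1; missing values as
    empty cells.
    """
    visit_rows = [
        {
            "patient_id": v.patient_id,
            "t_months": v.t_months,
            "fvc_pct_pred": v.fvc_pct_pred,
            "dlco_pct_pred": v.dlco_pct_pred,
        }
        for p in cohort
        for v in p.visits
    ]
    pd.DataFrame(visit_rows, columns=VISIT_COLUMNS).to_csv(visits_path, index=False)

    patient_rows = []
    for p in cohort:
        patient_rows.append(
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "disease_duration_years": p.disease_duration_years,
                "subtype": p.subtype,
                "ata": int(p.ata),
                "aca": int(p.aca),
                "ara": int(p.ara),
                "mrss": p.mrss,
                "reflux_dysphagia": int(p.reflux_dysphagia),
                "esr": p.esr,
                "crp_elevated": int(p.crp_elevated),
                "nyha_class": p.nyha_class,
                "immunosuppressant_use": (
                    "" if p.immunosuppressant_use is None else int(p.immunosuppressant_use)
                ),
                "died": int(p.died),
            }
        )
    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).to_csv(patients_path, index=False)


# Eligibility: the analysis population consists of adults with FVC and DLCO
# measured at baseline and at least one FVC measurement 12±3 months later.
# The first failing criterion, in this fixed order, is logged per patient.
_REASON_AGE = "age_under_18"
_REASON_BASE_FVC = "no_baseline_fvc"
_REASON_BASE_DLCO = "no_baseline_dlco"
_REASON_FOLLOWUP_FVC = "no_12m_fvc"

ELIGIBILITY_REASONS = (_REASON_AGE, _REASON_BASE_FVC, _REASON_BASE_DLCO, _REASON_FOLLOWUP_FVC)


def _eligibility_reason(
    patient: PatientRecord, interval_months: float, tolerance_months: float
) -> Optional[str]:
    if patient.age_years < 18:
        return _REASON_AGE
    base = patient.baseline
    if base is None or base.fvc_pct_pred is None:
        return _REASON_BASE_FVC
    if base.dlco_pct_pred is None:
        return _REASON_BASE_DLCO
    lo, hi = interval_months - tolerance_months, interval_months + tolerance_months
    has_followup = any(
        v.fvc_pct_pred is not None and lo <= v.t_months <= hi for v in patient.visits
    )
    if not has_followup:
        return _REASON_FOLLOWUP_FVC
    return None


def apply_eligibility(
    cohort: Cohort,
    interval_months: float = 12.0,
    tolerance_months: float = 3.0,
) -> tuple[Cohort, ExclusionLog]:
    """Retain adults with baseline FVC+DLCO and a follow-up FVC at 12±3 months.

    Returns the retained cohort and an :class:`ExclusionLog` with one reason
    code per excluded patient (the first failing criterion in the order
    age → baseline FVC → baseline DLCO → follow-up FVC).  The operation is
    idempotent and partitions the input: |retained| + |excluded| = |input|.
    """
    retained, log = [], ExclusionLog()
    for patient in cohort:
        reason = _eligibility_reason(patient, interval_months, tolerance_months)
        if reason is None:
            retained.append(patient)
        else:
            log.entries.append((patient.patient_id, reason))
    return Cohort(patients=retained, provenance=cohort.provenance), log
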
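"""Risk-factor models: 12-month progression logistic regression and a
linear mixed-effect model for 5-year FVC trajectories.

The contribution of this module is the model contracts and guards around
established estimation routines (statsmodels), not a bespoke optimiser:

* :func:`fit_progression_logistic` — maximum-likelihood logistic regression
  of significant progression in the initial 12-month period on baseline
  covariates, reported as odds ratios with Wald 95% CIs, with an
  events-per-variable (EPV) guard that warns when there are fewer than 10
  events per covariate;
* :func:`fit_fvc_trajectory_model` — REML linear mixed-effect model of FVC
  %-predicted over annual bins 0-5 years with per-patient random intercept
  and slope under an unstructured random-effect covariance, fixed effects
  for time, covariates and selected time-by-covariate interactions.  Only
  patients with at least three serial FVC measurements enter; a singular
  random-effect covariance triggers a flagged refit with independent
  variance components.

Coefficients are validated by simulation-based parameter recovery, never
against any particular registry's estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .classify import (
    PeriodCategory,
    Thresholds,
    DEFAULT_THRESHOLDS,
    classify_period_delta,
)
from .cohort import Cohort, PatientRecord
from .errors import ConvergenceError, DomainError
from .periods import build_periods, count_usable_fvc_measurements

EPV_REQUIRED = 10  # events per covariate required before the warning clears

#: Covariate name -> extractor over a PatientRecord.  Baseline lung function
#: comes from the t=0 visit.
COVARIATE_EXTRACTORS = {
    "male": lambda p: float(p.sex == "male"),
    "age_years": lambda p: p.age_years,
    "disease_duration_years": lambda p: p.disease_duration_years,
    "diffuse": lambda p: float(p.subtype == "diffuse"),
    "ata": lambda p: float(p.ata),
    "aca": lambda p: float(p.aca),
    "ara": lambda p: float(p.ara),
    "mrss": lambda p: float(p.mrss),
    "reflux_dysphagia": lambda p: float(p.reflux_dysphagia),
    "esr": lambda p: p.esr,
    "crp_elevated": lambda p: float(p.crp_elevated),
    "nyha_class": lambda p: float(p.nyha_class),
    "immunosuppressant_use": lambda p: (
        np.nan if p.immunosuppressant_use is None else float(p.immunosuppressant_use)
    ),
    "baseline_fvc": lambda p: (
        np.nan if p.baseline is None or p.baseline.fvc_pct_pred is None
        else p.baseline.fvc_pct_pred
    ),
    "baseline_dlco": lambda p: (
        np.nan if p.baseline is None or p.baseline.dlco_pct_pred is None
        else p.baseline.dlco_pct_pred
    ),
}


@dataclass
class LogisticSpec:
    """Covariate list for the 12-month significant-progression model.

    The covariate selection is an explicit input (mirroring expert-opinion
    selection in practice); no automated model selection is performed.
    """

    covariates: Sequence[str] = ("male", "age_years", "mrss", "reflux_dysphagia",
                                 "baseline_fvc")

    def __post_init__(self) -> None:
        unknown = [c for c in self.covariates if c not in COVARIATE_EXTRACTORS]
        if unknown:
            raise DomainError(f"unknown covariate(s): {unknown}")


@dataclass
class MixedModelSpec:
    """Fixed effects and interactions for the 5-year FVC trajectory model."""

    covariates: Sequence[str] = ("male", "mrss", "reflux_dysphagia")
    interactions: Sequence[str] = ("male", "mrss", "reflux_dysphagia")
    max_years: int = 5

    def __post_init__(self) -> None:
        unknown = [c for c in list(self.covariates) + list(self.interactions)
                   if c not in COVARIATE_EXTRACTORS]
        if unknown:
            raise DomainError(f"unknown covariate(s): {unknown}")
        missing = [c for c in self.interactions if c not in self.covariates]
        if missing:
            raise DomainError(
                f"interaction terms must also appear as main effects: {missing}"
            )


@dataclass
class RiskModelResult:
    """Per-term estimates with 95% CIs on the reported scale.

    ``table`` columns: term, estimate, ci_low, ci_high, p.  For the logistic
    model the scale is the odds ratio; for the mixed model, the coefficient
    in %-predicted points.  Warnings collect the EPV guard and any
    covariance downgrade; ``n_dropped`` counts complete-case exclusions.
    """

    table: pd.DataFrame
    scale: str
    converged: bool
    n_used: int
    n_dropped: int = 0
    n_events: Optional[int] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def epv_warning(self) -> bool:
        return any(w.startswith("events-per-variable") for w in self.warnings)

    def term(self, name: str) -> pd.Series:
        match = self.table[self.table["term"] == name]
        if match.empty:
            raise KeyError(f"no term {name!r} in result")
        return match.iloc[0]


def covariate_frame(cohort: Cohort, covariates: Sequence[str]) -> pd.DataFrame:
    """Patient-level covariate matrix in cohort order."""
    rows = {
        "patient_id": [p.patient_id for p in cohort],
    }
    for name in covariates:
        rows[name] = [COVARIATE_EXTRACTORS[name](p) for p in cohort]
    return pd.DataFrame(rows).set_index("patient_id")


def initial_progression_outcome(
    cohort: Cohort, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> pd.Series:
    """1 if the patient's initial period shows significant decline, 0 otherwise.

    Patients with no computable initial period get NaN (and are dropped by
    the logistic fit as outcome-missing).
    """
    values = {}
    for patient in cohort:
        periods = build_periods(patient, thresholds.interval_months, thresholds.tolerance_months)
        first = next((p for p in periods if p.index_k == 1), None)
        if first is None:
            values[patient.patient_id] = np.nan
        else:
            cat = classify_period_delta(first.delta_fvc, thresholds)
            values[patient.patient_id] = float(cat is PeriodCategory.SIGNIFICANT_DECLINE)
    return pd.Series(values, name="significant_progression")


def fit_logistic_frame(
    frame: pd.DataFrame, outcome: str, covariates: Sequence[str]
) -> RiskModelResult:
    """Maximum-likelihood logistic fit on a prepared frame.

    Complete-case: rows with any missing outcome/covariate are dropped and
    counted.  Complete separation raises :class:`ConvergenceError` rather
    than returning silent estimates.
    """
    cols = [outcome] + list(covariates)
    data = frame[cols].astype(float)
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)
    if data.empty:
        raise DomainError("no complete cases available for the logistic fit")

    y = data[outcome]
    X = sm.add_constant(data[list(covariates)], has_constant="add")
    n_events = int(y.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError or ConvergenceWarning
            raise ConvergenceError(f"logistic fit did not converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")

    conf = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": np.exp(fit.params.to_numpy()),
            "ci_low": np.exp(conf[0].to_numpy()),
            "ci_high": np.exp(conf[1].to_numpy()),
            "p": fit.pvalues.to_numpy(),
        }
    )
    table = table[table["term"] != "const"].reset_index(drop=True)

    result = RiskModelResult(
        table=table,
        scale="odds_ratio",
        converged=True,
        n_used=len(data),
        n_dropped=n_dropped,
        n_events=n_events,
    )
    if n_events < EPV_REQUIRED * len(covariates):
        result.warnings.append(
            f"events-per-variable below {EPV_REQUIRED}: {n_events} events for "
            f"{len(covariates)} covariates"
        )
    return result


def fit_progression_logistic(
    cohort: Cohort,
    spec: LogisticSpec,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> RiskModelResult:
    """Logistic regression of initial-period significant progression.

    Builds the outcome from classified initial periods, joins the baseline
    covariates and delegates to :func:`fit_logistic_frame`.
    """
    frame = covariate_frame(cohort, spec.covariates)
    frame["significant_progression"] = initial_progression_outcome(cohort, thresholds)
    return fit_logistic_frame(frame, "significant_progression", spec.covariates)


def select_long_term_subset(cohort: Cohort) -> tuple[Cohort, float]:
    """Patients with >= 3 serial FVC measurements, plus the retained fraction."""
    keep = [p.patient_id for p in cohort if count_usable_fvc_measurements(p) >= 3]
    fraction = len(keep) / len(cohort) if len(cohort) else float("nan")
    return cohort.subset(keep, provenance="long_term_subset"), fraction


def trajectory_frame(
    cohort: Cohort, spec: MixedModelSpec
) -> pd.DataFrame:
    """Long-format visit frame for the mixed model.

    One row per FVC measurement with time in annual bins (t_months/12
    rounded to the nearest integer year, capped at ``spec.max_years``),
    restricted to patients with >= 3 serial FVC measurements and
    complete covariates.
    """
    subset, _ = select_long_term_subset(cohort)
    if len(subset) == 0:
        raise DomainError("mixed model requires patients with >= 3 FVC measurements")
    cov = covariate_frame(subset, spec.covariates)
    rows = []
    for patient in subset:
        for visit in patient.visits:
            if visit.fvc_pct_pred is None:
                continue
            year = int(round(visit.t_months / 12.0))
            if year > spec.max_years:
                continue
            rows.append(
                {"patient_id": patient.patient_id, "time": float(year),
                 "fvc": visit.fvc_pct_pred}
            )
    frame = pd.DataFrame(rows).join(cov, on="patient_id")
    n_before = frame["patient_id"].nunique()
    frame = frame.dropna()
    frame.attrs["n_dropped_patients"] = n_before - frame["patient_id"].nunique()
    return frame


def fit_fvc_trajectory_model(
    cohort: Cohort,
    spec: MixedModelSpec,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> RiskModelResult:
    """REML mixed-effect fit of FVC over 0-5 years.

    Fixed effects: time, the spec'd covariates and time-by-covariate
    products; random effects: per-patient intercept and slope with an
    unstructured 2x2 covariance.  If the estimated random-effect covariance
    is singular, the model is refit with independent intercept and slope
    variances and the result is flagged.
    """
    frame = trajectory_frame(cohort, spec)
    terms = ["time"] + list(spec.covariates) + [f"time:{c}" for c in spec.interactions]
    formula = "fvc ~ " + " + ".join(terms)

    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = smf.mixedlm(formula, frame, groups=frame["patient_id"], re_formula="~time")
        fit = model.fit(reml=True)
        singular = np.linalg.eigvalsh(np.asarray(fit.cov_re)).min() < 1e-8
        if singular:
            notes.append(
                "singular unstructured random-effect covariance; refit with "
                "independent intercept and slope variances"
            )
            model = smf.mixedlm(
                formula,
                frame,
                groups=frame["patient_id"],
                re_formula="~1",
                vc_formula={"time": "0 + time"},
            )
            fit = model.fit(reml=True)

    fe = fit.fe_params
    conf = fit.conf_int(alpha=0.05).loc[fe.index]
    table = pd.DataFrame(
        {
            "term": fe.index,
            "estimate": fe.to_numpy(),
            "ci_low": conf[0].to_numpy(),
            "ci_high": conf[1].to_numpy(),
            "p": fit.pvalues.loc[fe.index].to_numpy(),
        }
    )
    table = table[table["term"] != "Intercept"].reset_index(drop=True)

    return RiskModelResult(
        table=table,
        scale="coefficient",
        converged=bool(fit.converged),
        n_used=frame["patient_id"].nunique(),
        n_dropped=int(frame.attrs.get("n_dropped_patients", 0)),
        warnings=notes,
    )
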
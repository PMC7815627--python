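"""Seeded synthetic registry-cohort generator and deterministic fixtures.

Real SSc-ILD registry data are not redistributable, so every downstream
stage is exercised on synthetic cohorts with known ground truth.  Two kinds
of synthetic data are produced:

* :func:`generate_cohort` — a stochastic registry emulator.  Each patient
  draws baseline covariates, a trajectory archetype (rapid decliner, slow
  decliner, stable, improver, fluctuating), and a latent linear FVC
  trajectory whose annual slope combines the archetype slope with additive
  covariate effects (male sex, skin score, reflux symptoms).  Visits are
  scheduled at annual anniversaries with Gaussian jitter, thinned by random
  missingness and truncated at a simulated death year; observed values add
  Gaussian measurement noise.  A truth table records each patient's
  archetype, latent slope and the noise-free category of every computable
  period, so classification can be checked against ground truth.

* fixture builders — noise-free, jitter-free cohorts realising exact
  classified counts (an initial-period split, a full overall-course by
  episode-column grid, or the composite headline cohort), used to verify
  that the pipeline reproduces published count-and-percentage tables.

Identical (config, seed) pairs produce byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .classify import (
    EpisodeColumn,
    OverallCategory,
    PeriodCategory,
    Thresholds,
    DEFAULT_THRESHOLDS,
    classify_period_delta,
)
from .cohort import Cohort, PatientRecord, Visit
from .errors import ConfigError, FeasibilityError
from . import reference


@dataclass(frozen=True)
class ArchetypeSpec:
    """One trajectory archetype in the generator's mixture.

    ``annual_slope_mean``/``annual_slope_sd`` are %-predicted points per
    year; ``fluctuation_amplitude`` adds a zero-mean sinusoid with a ~2-year
    period, producing alternating decline and improvement periods with no
    net trend.
    """

    name: str
    annual_slope_mean: float
    annual_slope_sd: float
    fluctuation_amplitude: float
    weight: float

    def __post_init__(self) -> None:
        if self.annual_slope_sd < 0 or self.fluctuation_amplitude < 0 or self.weight < 0:
            raise ConfigError(f"archetype {self.name!r}: sd, amplitude and weight must be >= 0")


DEFAULT_ARCHETYPES = (
    ArchetypeSpec("rapid_decliner", -12.0, 2.0, 0.0, 0.08),
    ArchetypeSpec("slow_decliner", -3.0, 1.5, 0.0, 0.22),
    ArchetypeSpec("stable", 0.0, 1.5, 0.0, 0.40),
    ArchetypeSpec("improver", 4.0, 1.5, 0.0, 0.15),
    ArchetypeSpec("fluctuating", 0.0, 1.0, 8.0, 0.15),
)


@dataclass(frozen=True)
class CovariateEffects:
    """Additive effects on the annual FVC slope (points/year).

    Defaults mirror the published multivariable time-interaction
    coefficients for a real-world SSc-ILD cohort: male sex -1.30, each mRSS
    point -0.06 and reflux/dysphagia symptoms -0.72 points/year.
    """

    male: float = -1.30
    mrss_per_point: float = -0.06
    reflux: float = -0.72


# Baseline covariate prevalences of the emulated registry population.
DEFAULT_COVARIATE_PREVALENCE = {
    "male": 0.18,
    "diffuse": 0.50,
    "ata": 0.53,
    "aca": 0.18,
    "ara": 0.05,
    "reflux_dysphagia": 0.67,
    "crp_elevated": 0.27,
    "immunosuppressant_use": 0.37,
}

# NYHA functional class distribution (classes 1-4).
DEFAULT_NYHA_PROBS = (0.4554, 0.3977, 0.1292, 0.0177)


@dataclass
class SyntheticConfig:
    """Full parameterisation of the registry emulator.

    Baseline FVC 87 (SD 21.1) and DLCO 59 (SD 18.3) %-predicted and the
    5-year follow-up match the emulated registry population.  The
    within-patient measurement noise SD (default 3 points) is a free
    parameter: registry lung-function measurement error is not published.
    """

    n_patients: int = 500
    follow_up_years: int = 5
    visit_jitter_sd_months: float = 1.0
    p_missing_visit: float = 0.15
    p_missing_dlco: float = 0.30
    measurement_noise_sd: float = 3.0
    baseline_fvc_mean: float = 87.0
    baseline_fvc_sd: float = 21.1
    baseline_dlco_mean: float = 59.0
    baseline_dlco_sd: float = 18.3
    dlco_slope_ratio: float = 0.6
    death_base_rate: float = 0.02
    death_slope_factor: float = 0.10
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    covariate_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    nyha_probs: tuple = DEFAULT_NYHA_PROBS
    archetypes: tuple = DEFAULT_ARCHETYPES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("visit_jitter_sd_months", "measurement_noise_sd", "baseline_fvc_sd",
                     "baseline_dlco_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_missing_visit", "p_missing_dlco", "death_base_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for key, p in self.covariate_prevalence.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"covariate_prevalence[{key!r}] must be in [0, 1]")
        total = sum(a.weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"archetype weights must sum to 1, got {total}")
        if abs(sum(self.nyha_probs) - 1.0) > 1e-6:
            raise ConfigError("nyha_probs must sum to 1")

    def to_yaml(self) -> str:
        data = asdict(self)
        data["archetypes"] = [asdict(a) for a in self.archetypes]
        data["covariate_effects"] = asdict(self.covariate_effects)
        data["nyha_probs"] = list(self.nyha_probs)
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        data = yaml.safe_load(text) or {}
        if "archetypes" in data:
            data["archetypes"] = tuple(ArchetypeSpec(**a) for a in data["archetypes"])
        if "covariate_effects" in data:
            data["covariate_effects"] = CovariateEffects(**data["covariate_effects"])
        if "nyha_probs" in data:
            data["nyha_probs"] = tuple(data["nyha_probs"])
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth for a generated cohort.

    ``patients`` has one row per patient (archetype, latent annual slope,
    death year); ``periods`` has one row per noise-free computable period
    (index_k, true delta, true category).
    """

    patients: pd.DataFrame
    periods: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        if self.periods.empty:
            return self.patients.copy()
        return self.periods.merge(self.patients, on="patient_id", how="left")


def generate_cohort(
    config: SyntheticConfig, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[Cohort, TruthTable]:
    """Draw a synthetic registry cohort and its ground truth.

    The latent trajectory is
    ``FVC(t) = baseline + slope * t/12 + A * sin(2*pi*t/24 + phase)`` with t
    in months; observed values add N(0, noise_sd) and are truncated to
    [10, 160] %-predicted.  Death is administrative truncation: an annual
    hazard scaled up for steeper decline removes all visits from the death
    year onward.
    """
    rng = np.random.default_rng(config.seed)
    prev = config.covariate_prevalence
    eff = config.covariate_effects
    weights = np.array([a.weight for a in config.archetypes])

    patients: list[PatientRecord] = []
    truth_patient_rows = []
    truth_period_rows = []

    for i in range(config.n_patients):
        pid = f"S{i:05d}"
        male = rng.random() < prev["male"]
        age = float(np.clip(rng.normal(56.0, 13.1), 18.0, 90.0))
        duration = float(np.clip(rng.normal(9.7, 8.3), 0.1, 50.0))
        diffuse = rng.random() < prev["diffuse"]
        ata = rng.random() < prev["ata"]
        aca = rng.random() < prev["aca"]
        ara = rng.random() < prev["ara"]
        mrss = int(np.clip(round(rng.normal(10.0, 8.1)), 0, 51))
        reflux = rng.random() < prev["reflux_dysphagia"]
        esr = float(np.clip(rng.normal(26.0, 20.6), 1.0, 120.0))
        crp = rng.random() < prev["crp_elevated"]
        nyha = int(rng.choice(4, p=np.asarray(config.nyha_probs) / sum(config.nyha_probs)) + 1)
        immuno = rng.random() < prev["immunosuppressant_use"]

        arch_idx = int(rng.choice(len(config.archetypes), p=weights / weights.sum()))
        arch = config.archetypes[arch_idx]
        slope = float(rng.normal(arch.annual_slope_mean, arch.annual_slope_sd))
        slope += eff.male * male + eff.mrss_per_point * mrss + eff.reflux * reflux
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        amp = arch.fluctuation_amplitude

        b_fvc = float(np.clip(rng.normal(config.baseline_fvc_mean, config.baseline_fvc_sd),
                              30.0, 160.0))
        b_dlco = float(np.clip(rng.normal(config.baseline_dlco_mean, config.baseline_dlco_sd),
                               15.0, 140.0))

        def latent_fvc(t: float) -> float:
            return b_fvc + slope * t / 12.0 + amp * math.sin(2.0 * math.pi * t / 24.0 + phase)

        def latent_dlco(t: float) -> float:
            return b_dlco + config.dlco_slope_ratio * slope * t / 12.0

        # Death: annual Bernoulli, hazard inflated for steeper decline.
        annual_p = min(0.5, config.death_base_rate * math.exp(-config.death_slope_factor * slope))
        death_year: Optional[int] = None
        for year in range(1, config.follow_up_years + 1):
            if rng.random() < annual_p and death_year is None:
                death_year = year

        # Visit schedule: baseline plus jittered anniversaries, with dropout.
        # All random draws happen for every scheduled visit so the stream is
        # identical whether or not a visit is retained.
        present: dict[int, float] = {0: 0.0}
        obs_noise: dict[int, tuple[float, float, bool]] = {}
        for k in range(1, config.follow_up_years + 1):
            jitter = float(np.clip(rng.normal(0.0, config.visit_jitter_sd_months), -5.0, 5.0))
            missing = rng.random() < config.p_missing_visit
            dlco_missing = rng.random() < config.p_missing_dlco
            noise_f = float(rng.normal(0.0, config.measurement_noise_sd))
            noise_d = float(rng.normal(0.0, config.measurement_noise_sd))
            if missing or (death_year is not None and k >= death_year):
                continue
            present[k] = 12.0 * k + jitter
            obs_noise[k] = (noise_f, noise_d, dlco_missing)

        noise0_f = float(rng.normal(0.0, config.measurement_noise_sd))
        noise0_d = float(rng.normal(0.0, config.measurement_noise_sd))

        visits = [
            Visit(
                patient_id=pid,
                t_months=0.0,
                fvc_pct_pred=float(np.clip(latent_fvc(0.0) + noise0_f, 10.0, 160.0)),
                dlco_pct_pred=float(np.clip(latent_dlco(0.0) + noise0_d, 5.0, 150.0)),
            )
        ]
        for k in sorted(k for k in present if k > 0):
            t_k = present[k]
            noise_f, noise_d, dlco_missing = obs_noise[k]
            visits.append(
                Visit(
                    patient_id=pid,
                    t_months=t_k,
                    fvc_pct_pred=float(np.clip(latent_fvc(t_k) + noise_f, 10.0, 160.0)),
                    dlco_pct_pred=(
                        None
                        if dlco_missing
                        else float(np.clip(latent_dlco(t_k) + noise_d, 5.0, 150.0))
                    ),
                )
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                age_years=age,
                sex="male" if male else "female",
                disease_duration_years=duration,
                subtype="diffuse" if diffuse else "limited",
                ata=ata,
                aca=aca,
                ara=ara,
                mrss=mrss,
                reflux_dysphagia=reflux,
                esr=esr,
                crp_elevated=crp,
                nyha_class=nyha,
                immunosuppressant_use=immuno,
                died=death_year is not None,
                visits=visits,
            )
        )
        truth_patient_rows.append(
            {
                "patient_id": pid,
                "archetype": arch.name,
                "latent_slope": slope,
                "death_year": death_year,
            }
        )

        # Noise-free period truth over anniversary pairs present within the
        # matching window, mirroring the period-builder's chaining rule.
        # Latent values pass through the same physiological truncation as
        # observations, so at zero noise the pipeline agrees exactly.
        for k in sorted(present):
            if k == 0 or (k - 1) not in present:
                continue
            t_end, t_start = present[k], present[k - 1]
            if abs(t_end - 12.0 * k) > thresholds.tolerance_months:
                continue
            if k - 1 > 0 and abs(t_start - 12.0 * (k - 1)) > thresholds.tolerance_months:
                continue
            true_delta = float(
                np.clip(latent_fvc(t_end), 10.0, 160.0)
                - np.clip(latent_fvc(t_start), 10.0, 160.0)
            )
            truth_period_rows.append(
                {
                    "patient_id": pid,
                    "index_k": k,
                    "true_delta": true_delta,
                    "true_category": classify_period_delta(true_delta, thresholds).value,
                }
            )

    truth = TruthTable(
        patients=pd.DataFrame(
            truth_patient_rows, columns=["patient_id", "archetype", "latent_slope", "death_year"]
        ),
        periods=pd.DataFrame(
            truth_period_rows, columns=["patient_id", "index_k", "true_delta", "true_category"]
        ),
    )
    return Cohort(patients=patients, provenance=f"synthetic(seed={config.seed})"), truth


def simulate_binary_outcomes(
    covariates: pd.DataFrame, coefs: dict[str, float], intercept: float, seed: int
) -> pd.Series:
    """Draw Bernoulli outcomes from a logistic model over given covariates.

    Used by the parameter-recovery harness: the true log-odds are
    ``intercept + sum(coefs[c] * covariates[c])``.
    """
    rng = np.random.default_rng(seed)
    eta = np.full(len(covariates), float(intercept))
    for name, beta in coefs.items():
        eta = eta + beta * covariates[name].to_numpy(dtype=float)
    return pd.Series(rng.random(len(covariates)) < expit(eta), index=covariates.index).astype(int)


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

# Representative per-period FVC deltas, one per category (the published
# subgroup means of the emulated cohort).
REPRESENTATIVE_DELTAS = {
    PeriodCategory.SIGNIFICANT_DECLINE: -18.0,
    PeriodCategory.MODERATE_DECLINE: -7.0,
    PeriodCategory.STABLE: 0.3,
    PeriodCategory.IMPROVEMENT: 12.0,
}

_FIXTURE_BASELINE_FVC = 90.0
_FIXTURE_BASELINE_DLCO = 59.0


def _fixture_patient(pid: str, deltas: list[float], died: bool = False) -> PatientRecord:
    """Noise-free patient with annual visits realising the given period deltas."""
    fvc = _FIXTURE_BASELINE_FVC
    visits = [Visit(pid, 0.0, fvc, _FIXTURE_BASELINE_DLCO)]
    for k, d in enumerate(deltas, start=1):
        fvc += d
        visits.append(Visit(pid, 12.0 * k, fvc, None))
    return PatientRecord(
        patient_id=pid,
        age_years=55.0,
        sex="female",
        disease_duration_years=9.7,
        subtype="limited",
        ata=False,
        aca=False,
        ara=False,
        mrss=10,
        reflux_dysphagia=False,
        esr=26.0,
        crp_elevated=False,
        nyha_class=1,
        immunosuppressant_use=None,
        died=died,
        visits=visits,
    )


def make_initial_period_fixture(
    counts: dict[PeriodCategory, int], id_prefix: str = "I"
) -> Cohort:
    """Two-visit cohort whose initial-period classification realises `counts`."""
    patients = []
    i = 0
    for cat, n in counts.items():
        if n < 0:
            raise FeasibilityError(f"negative count for {cat}")
        for _ in range(n):
            patients.append(_fixture_patient(f"{id_prefix}{i:05d}", [REPRESENTATIVE_DELTAS[cat]]))
            i += 1
    return Cohort(patients=patients, provenance="fixture:initial_period")


# Overall-course target deltas (sum of period deltas) per row, and the
# decline periods that define each episode column.
_ROW_TARGET = {
    OverallCategory.IMPROVEMENT: 7.0,
    OverallCategory.STABLE: 0.0,
    OverallCategory.MODERATE_DECLINE: -7.0,
    OverallCategory.SIGNIFICANT_DECLINE: -15.0,
    OverallCategory.MAJOR_DECLINE: -25.0,
}
_COLUMN_DECLINES = {
    EpisodeColumn.NO_DECLINE: [],
    EpisodeColumn.ONE_MODERATE: [-7.0],
    EpisodeColumn.ONE_SIGNIFICANT: [-12.0],
    EpisodeColumn.MULTI_ONLY_MODERATE: [-7.0, -7.0],
    EpisodeColumn.MIXED_SIG_AND_MOD: [-12.0, -7.0],
    EpisodeColumn.MULTI_ONLY_SIGNIFICANT: [-12.0, -12.0],
}


def _cell_deltas(
    row: OverallCategory, col: EpisodeColumn, max_periods: Optional[int]
) -> list[float]:
    """Period-delta sequence classifying into exactly (row, col).

    Starts from the column's decline periods, pads with stable -4 steps
    while the remainder would itself be a decline, then closes with one
    stable/improving period that lands the cumulative change on the row's
    target.
    """
    deltas = list(_COLUMN_DECLINES[col])
    remainder = _ROW_TARGET[row] - sum(deltas)
    while remainder <= -5.0:
        deltas.append(-4.0)
        remainder += 4.0
    deltas.append(remainder)
    if len(deltas) < 2:
        deltas.append(0.0)
    if max_periods is not None and len(deltas) > max_periods:
        raise FeasibilityError(
            f"cell ({row.value}, {col.value}) needs {len(deltas)} periods, "
            f"more than max_periods={max_periods}"
        )
    return deltas


def make_table_fixture(
    cell_counts: dict[OverallCategory, dict[EpisodeColumn, int]],
    max_periods: Optional[int] = None,
    id_prefix: str = "T",
) -> Cohort:
    """Noise-free cohort realising exact (overall course x episode column) counts.

    Every patient has annual visits from baseline, >= 2 periods and >= 3 FVC
    measurements, so the whole fixture is the long-term analysis subset.
    Raises :class:`FeasibilityError` naming the first unrealisable cell.
    """
    patients = []
    i = 0
    for row, cols in cell_counts.items():
        for col, n in cols.items():
            if n < 0:
                raise FeasibilityError(f"negative count for cell ({row.value}, {col.value})")
            if n == 0:
                continue
            deltas = _cell_deltas(row, col, max_periods)
            for _ in range(n):
                patients.append(_fixture_patient(f"{id_prefix}{i:05d}", deltas))
                i += 1
    return Cohort(patients=patients, provenance="fixture:crosstab")


# Recipes for the composite headline cohort: (count, period deltas).
# The long-term block reproduces the published overall-course, episode and
# pattern counts; the two-visit block tops up the initial-period split.
_HEADLINE_LONG_TERM_RECIPES = [
    (16, [-13.0, -13.0]),                      # major decline, rapid
    (20, [-4.0, -12.0, -11.0]),                # major decline, progressive
    (13, [-4.0, -4.0, -4.0, -11.0, -11.0]),    # major decline, slow
    (30, [-1.0, -7.0, -7.0]),                  # significant decline, progressive
    (45, [-1.0, -1.0, -1.0, -6.0, -6.0]),      # significant decline, slow
    (18, [-1.0, -6.0]),                        # moderate decline, progressive (tie)
    (58, [0.0, 0.0, -7.0]),                    # moderate decline, slow
    (99, [0.0, 0.0]),                          # stable, no decline episode
    (107, [6.0, -6.0]),                        # stable, one moderate episode
    (79, [3.0, 3.0]),                          # improvement, no decline episode
    (50, [12.0, -5.0]),                        # improvement, one moderate episode
]
_HEADLINE_TWO_VISIT_RECIPES = [
    (84, [REPRESENTATIVE_DELTAS[PeriodCategory.SIGNIFICANT_DECLINE]]),
    (123, [REPRESENTATIVE_DELTAS[PeriodCategory.MODERATE_DECLINE]]),
    (34, [REPRESENTATIVE_DELTAS[PeriodCategory.STABLE]]),
    (50, [REPRESENTATIVE_DELTAS[PeriodCategory.IMPROVEMENT]]),
]


def make_headline_fixture() -> Cohort:
    """826-patient deterministic cohort reproducing every headline count.

    Initial-period split 100/123/396/207, 535 long-term patients, overall
    course 49/75/76/206/129, 178 patients without any decline episode,
    pattern split 16/68/116 among the 200 overall decliners, and 85 deaths
    distributed over initial-period categories.
    """
    patients: list[PatientRecord] = []
    i = 0
    for count, deltas in _HEADLINE_LONG_TERM_RECIPES + _HEADLINE_TWO_VISIT_RECIPES:
        for _ in range(count):
            patients.append(_fixture_patient(f"H{i:05d}", deltas))
            i += 1

    # Flag deaths per initial-period category, first-come deterministic.
    remaining = {
        cat.value: n for cat, n in reference.DEATHS_BY_INITIAL_CATEGORY.items()
    }
    for patient in patients:
        first_delta = patient.visits[1].fvc_pct_pred - patient.visits[0].fvc_pct_pred
        cat = classify_period_delta(first_delta).value
        if remaining.get(cat, 0) > 0:
            patient.died = True
            remaining[cat] -= 1
    return Cohort(patients=patients, provenance="fixture:headline")
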
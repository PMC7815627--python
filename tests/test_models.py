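"""Risk-model contracts: logistic progression model and FVC mixed model."""

import numpy as np
import pandas as pd
import pytest

from ildtraj import (
    ArchetypeSpec,
    Cohort,
    CovariateEffects,
    LogisticSpec,
    MixedModelSpec,
    SyntheticConfig,
    fit_fvc_trajectory_model,
    fit_logistic_frame,
    fit_progression_logistic,
    generate_cohort,
    initial_progression_outcome,
    select_long_term_subset,
    simulate_binary_outcomes,
)
from ildtraj.errors import ConvergenceError, DomainError

from conftest import make_patient


class TestLogistic:
    def test_two_by_two_matches_closed_form_odds_ratio(self):
        """On a saturated binary design the MLE equals the contingency-table OR."""
        # exposed: 30/70 events; unexposed: 10/90 events
        rows = (
            [{"x": 1.0, "y": 1.0}] * 30 + [{"x": 1.0, "y": 0.0}] * 70
            + [{"x": 0.0, "y": 1.0}] * 10 + [{"x": 0.0, "y": 0.0}] * 90
        )
        frame = pd.DataFrame(rows)
        result = fit_logistic_frame(frame, "y", ["x"])
        closed_form = (30 * 90) / (70 * 10)  # ad/bc
        assert result.term("x")["estimate"] == pytest.approx(closed_form, abs=1e-6)
        assert result.term("x")["ci_low"] <= closed_form <= result.term("x")["ci_high"]

    def test_epv_warning_raised_when_events_scarce(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "a": rng.normal(size=300),
                "b": rng.normal(size=300),
                "c": rng.normal(size=300),
            }
        )
        # ~25 events for 3 covariates -> fewer than 10 per covariate
        frame["y"] = (rng.random(300) < 25 / 300).astype(float)
        result = fit_logistic_frame(frame, "y", ["a", "b", "c"])
        assert result.epv_warning
        assert result.n_events < 30

    def test_complete_separation_raises(self):
        frame = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                              "y": np.r_[np.zeros(20), np.ones(20)]})
        with pytest.raises(ConvergenceError):
            fit_logistic_frame(frame, "y", ["x"])

    def test_complete_case_dropping_counted(self):
        frame = pd.DataFrame({"x": [0.0, 1.0, np.nan, 1.0, 0.0] * 20,
                              "y": [0.0, 1.0, 1.0, 0.0, 1.0] * 20})
        result = fit_logistic_frame(frame, "y", ["x"])
        assert result.n_dropped == 20
        assert result.n_used == 80

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"x": rng.normal(size=200)})
        frame["y"] = (rng.random(200) < 0.3).astype(float)
        a = fit_logistic_frame(frame, "y", ["x"])
        b = fit_logistic_frame(frame.sample(frac=1.0, random_state=2), "y", ["x"])
        assert a.term("x")["estimate"] == pytest.approx(b.term("x")["estimate"], rel=1e-9)

    def test_cohort_outcome_derived_from_initial_period(self):
        patients = [
            make_patient("A", [(0, 90, 60), (12, 75)]),   # -15: significant
            make_patient("B", [(0, 90, 60), (12, 83)]),   # -7: moderate, not the outcome
            make_patient("C", [(0, 90, 60), (20, 80)]),   # no initial period
        ]
        outcome = initial_progression_outcome(Cohort(patients=patients))
        assert outcome["A"] == 1.0
        assert outcome["B"] == 0.0
        assert np.isnan(outcome["C"])

    def test_true_odds_ratio_recovered_at_large_n(self):
        rng = np.random.default_rng(21)
        n = 5000
        covariates = pd.DataFrame({"reflux_dysphagia": (rng.random(n) < 0.5).astype(float)})
        y = simulate_binary_outcomes(
            covariates, {"reflux_dysphagia": np.log(2.0)}, intercept=-1.1, seed=22
        )
        frame = covariates.assign(y=y)
        result = fit_logistic_frame(frame, "y", ["reflux_dysphagia"])
        assert 1.7 <= result.term("reflux_dysphagia")["estimate"] <= 2.4


class TestLongTermSubset:
    def test_filters_on_three_fvc_measurements(self):
        patients = [
            make_patient("A", [(0, 90, 60), (12, 85), (24, 80)]),
            make_patient("B", [(0, 90, 60), (12, 85)]),
        ]
        subset, fraction = select_long_term_subset(Cohort(patients=patients))
        assert [p.patient_id for p in subset] == ["A"]
        assert fraction == pytest.approx(0.5)

    def test_empty_cohort(self):
        subset, fraction = select_long_term_subset(Cohort(patients=[]))
        assert len(subset) == 0 and np.isnan(fraction)


def _recovery_config(n_patients, seed, male_effect=-1.3, noise=2.0):
    return SyntheticConfig(
        n_patients=n_patients,
        measurement_noise_sd=noise,
        p_missing_visit=0.10,
        covariate_effects=CovariateEffects(male=male_effect, mrss_per_point=0.0, reflux=0.0),
        covariate_prevalence={
            "male": 0.5, "diffuse": 0.5, "ata": 0.5, "aca": 0.2, "ara": 0.05,
            "reflux_dysphagia": 0.5, "crp_elevated": 0.3, "immunosuppressant_use": 0.4,
        },
        archetypes=(ArchetypeSpec("stable", -1.0, 1.5, 0.0, 1.0),),
        seed=seed,
    )


class TestMixedModel:
    def test_noise_free_common_slope_recovered_exactly(self):
        """With no noise and a shared slope the time coefficient is the slope."""
        patients = [
            make_patient(f"P{i}", [(12 * k, 90.0 + 5 * i - 2.0 * k) for k in range(4)])
            for i in range(12)
        ]
        cohort = Cohort(patients=patients)
        spec = MixedModelSpec(covariates=(), interactions=())
        result = fit_fvc_trajectory_model(cohort, spec)
        # degenerate (zero-variance-slope) data caps attainable optimizer precision
        assert result.term("time")["estimate"] == pytest.approx(-2.0, abs=1e-3)

    def test_time_by_sex_interaction_recovered(self):
        cohort, _ = generate_cohort(_recovery_config(n_patients=500, seed=31))
        spec = MixedModelSpec(covariates=("male",), interactions=("male",))
        result = fit_fvc_trajectory_model(cohort, spec)
        assert result.term("time:male")["estimate"] == pytest.approx(-1.3, abs=0.4)

    def test_null_interaction_near_zero(self):
        cohort, _ = generate_cohort(
            _recovery_config(n_patients=500, seed=32, male_effect=0.0)
        )
        spec = MixedModelSpec(covariates=("male",), interactions=("male",))
        result = fit_fvc_trajectory_model(cohort, spec)
        assert abs(result.term("time:male")["estimate"]) < 0.3

    def test_requires_three_serial_measurements(self):
        patients = [make_patient("A", [(0, 90, 60), (12, 85)])]
        with pytest.raises(DomainError, match=">= 3"):
            fit_fvc_trajectory_model(
                Cohort(patients=patients), MixedModelSpec(covariates=(), interactions=())
            )

    def test_patient_order_invariance(self):
        cohort, _ = generate_cohort(_recovery_config(n_patients=120, seed=33))
        reversed_cohort = Cohort(patients=list(reversed(cohort.patients)))
        spec = MixedModelSpec(covariates=("male",), interactions=("male",))
        a = fit_fvc_trajectory_model(cohort, spec)
        b = fit_fvc_trajectory_model(reversed_cohort, spec)
        assert a.term("time:male")["estimate"] == pytest.approx(
            b.term("time:male")["estimate"], abs=1e-6
        )

    def test_interaction_must_have_main_effect(self):
        with pytest.raises(DomainError):
            MixedModelSpec(covariates=(), interactions=("male",))
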
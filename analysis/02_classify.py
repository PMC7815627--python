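#!/usr/bin/env python
"""Classify the simulated cohort: eligibility, periods, all taxonomies.

Reads the cohort written by 01_simulate.py, applies the eligibility filter
(adults, baseline FVC+DLCO, follow-up FVC at 12±3 months), anchors annual
periods, classifies every period and patient, and writes the derived tables:
classified periods, per-patient summary, per-period prevalence, the
transition matrix over consecutive periods, and the overall-course by
episode-history cross-tabulation.
"""

import argparse
from pathlib import Path

from ildtraj import (
    apply_eligibility,
    cohort_periods,
    crosstab_overall_by_episode,
    patient_summary,
    period_prevalence,
    periods_frame,
    read_cohort,
    transition_counts,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
parser.add_argument("--out", type=Path, default=Path("results/classified"))
args = parser.parse_args()

cohort = read_cohort(args.data / "visits.csv", args.data / "patients.csv")
eligible, exclusions = apply_eligibility(cohort)
print(f"{len(eligible)}/{len(cohort)} patients eligible; exclusions by reason:")
if len(exclusions):
    print(exclusions.to_frame()["reason_code"].value_counts().to_string())

args.out.mkdir(parents=True, exist_ok=True)
exclusions.to_frame().to_csv(args.out / "exclusions.csv", index=False)

by_patient = cohort_periods(eligible)
frame = periods_frame(by_patient)
frame.to_csv(args.out / "classified_periods.csv", index=False)
print(f"\n{len(frame)} classified periods; category mix:")
print(frame["category"].value_counts(normalize=True).round(3).to_string())

patient_summary(eligible).to_csv(args.out / "patient_summary.csv", index=False)
prevalence = period_prevalence(by_patient)
prevalence.to_csv(args.out / "period_prevalence.csv", index=False)
print("\nper-period prevalence (fractions):")
print(prevalence.round(3).to_string(index=False))

matrix = transition_counts(by_patient)
matrix.to_csv(args.out / "transition_matrix.csv")
print(f"\ntransition matrix over {matrix.to_numpy().sum()} consecutive pairs:")
print(matrix.to_string())

counts, pct = crosstab_overall_by_episode(eligible)
counts.to_csv(args.out / "crosstab_counts.csv")
pct.to_csv(args.out / "crosstab_column_pct.csv")
print("\noverall course x episode history (counts):")
print(counts.to_string())
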
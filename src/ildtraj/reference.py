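"""Published EUSTAR SSc-ILD cohort counts used as deterministic fixture targets.

These are the headline counts reported for the 826-patient EUSTAR SSc-ILD
progression cohort: the initial 12-month period classification, the
long-term (>= 3 FVC measurements) subset, the overall-course distribution,
the cross-tabulation of overall course by decline-episode history, the
progression-pattern split among overall decliners, and all-cause deaths.
They parameterise the fixture builders in :mod:`ildtraj.simulate`, which
construct synthetic trajectories realising exactly these classified counts;
they are inputs to fixtures, never outputs of this package.
"""

from .classify import EpisodeColumn, OverallCategory, PatternLabel, PeriodCategory

TOTAL_PATIENTS = 826
LONG_TERM_PATIENTS = 535
DEATHS_TOTAL = 85

# Classification of the initial 12±3-month period, all 826 patients.
INITIAL_PERIOD_COUNTS = {
    PeriodCategory.SIGNIFICANT_DECLINE: 100,
    PeriodCategory.MODERATE_DECLINE: 123,
    PeriodCategory.STABLE: 396,
    PeriodCategory.IMPROVEMENT: 207,
}

# Deaths by initial-period category (improvement count derived as the
# remainder of the 85 total deaths).
DEATHS_BY_INITIAL_CATEGORY = {
    PeriodCategory.SIGNIFICANT_DECLINE: 11,
    PeriodCategory.MODERATE_DECLINE: 18,
    PeriodCategory.STABLE: 36,
    PeriodCategory.IMPROVEMENT: 20,
}

# Overall course (first-to-last FVC) among the 535 long-term patients.
OVERALL_COURSE_COUNTS = {
    OverallCategory.MAJOR_DECLINE: 49,
    OverallCategory.SIGNIFICANT_DECLINE: 75,
    OverallCategory.MODERATE_DECLINE: 76,
    OverallCategory.STABLE: 206,
    OverallCategory.IMPROVEMENT: 129,
}

# Pattern split among the 200 patients with an overall decline (moderate,
# significant or major).  The rapid count is published directly (16 = 8%);
# the progressive/slow counts are derived from the published 34%/58% split.
PATTERN_COUNTS_AMONG_DECLINERS = {
    PatternLabel.RAPID: 16,
    PatternLabel.PROGRESSIVE: 68,
    PatternLabel.SLOW: 116,
}

# Cross-tabulation of overall course (rows) by decline-episode column among
# the 535 long-term patients.  Blank published cells are zeros.
CROSSTAB_COUNTS = {
    OverallCategory.IMPROVEMENT: {
        EpisodeColumn.NO_DECLINE: 79,
        EpisodeColumn.ONE_MODERATE: 22,
        EpisodeColumn.ONE_SIGNIFICANT: 21,
        EpisodeColumn.MULTI_ONLY_MODERATE: 1,
        EpisodeColumn.MIXED_SIG_AND_MOD: 3,
        EpisodeColumn.MULTI_ONLY_SIGNIFICANT: 3,
    },
    OverallCategory.STABLE: {
        EpisodeColumn.NO_DECLINE: 99,
        EpisodeColumn.ONE_MODERATE: 59,
        EpisodeColumn.ONE_SIGNIFICANT: 29,
        EpisodeColumn.MULTI_ONLY_MODERATE: 13,
        EpisodeColumn.MIXED_SIG_AND_MOD: 1,
        EpisodeColumn.MULTI_ONLY_SIGNIFICANT: 5,
    },
    OverallCategory.MODERATE_DECLINE: {
        EpisodeColumn.NO_DECLINE: 0,
        EpisodeColumn.ONE_MODERATE: 28,
        EpisodeColumn.ONE_SIGNIFICANT: 17,
        EpisodeColumn.MULTI_ONLY_MODERATE: 25,
        EpisodeColumn.MIXED_SIG_AND_MOD: 1,
        EpisodeColumn.MULTI_ONLY_SIGNIFICANT: 5,
    },
    OverallCategory.SIGNIFICANT_DECLINE: {
        EpisodeColumn.NO_DECLINE: 0,
        EpisodeColumn.ONE_MODERATE: 2,
        EpisodeColumn.ONE_SIGNIFICANT: 29,
        EpisodeColumn.MULTI_ONLY_MODERATE: 23,
        EpisodeColumn.MIXED_SIG_AND_MOD: 10,
        EpisodeColumn.MULTI_ONLY_SIGNIFICANT: 11,
    },
    OverallCategory.MAJOR_DECLINE: {
        EpisodeColumn.NO_DECLINE: 0,
        EpisodeColumn.ONE_MODERATE: 2,
        EpisodeColumn.ONE_SIGNIFICANT: 11,
        EpisodeColumn.MULTI_ONLY_MODERATE: 3,
        EpisodeColumn.MIXED_SIG_AND_MOD: 10,
        EpisodeColumn.MULTI_ONLY_SIGNIFICANT: 23,
    },
}

# Episode-column totals implied by the cross-tabulation (no-decline = 178).
NO_DECLINE_PATIENTS = 178
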
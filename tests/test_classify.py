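"""Threshold classifiers, taxonomies and cohort-level aggregations."""

import numpy as np
import pytest

from ildtraj import (
    Cohort,
    EpisodeColumn,
    OverallCategory,
    PatternLabel,
    PeriodCategory,
    assign_episode_column,
    classify_overall_course,
    classify_pattern,
    classify_period_delta,
    cohort_periods,
    crosstab_overall_by_episode,
    is_progressive_combined,
    mortality_summary,
    period_prevalence,
    round_half_up,
    transition_counts,
)
from ildtraj.errors import DomainError

from conftest import make_patient

SIG = PeriodCategory.SIGNIFICANT_DECLINE
MOD = PeriodCategory.MODERATE_DECLINE
STA = PeriodCategory.STABLE
IMP = PeriodCategory.IMPROVEMENT


class TestPeriodDelta:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (-18.0, SIG),           # subgroup mean of the significant bin
            (-10.001, SIG),
            (-10.0, MOD),           # bin edge: -10 belongs to moderate
            (-7.0, MOD),
            (-5.0, MOD),            # bin edge: -5 belongs to moderate
            (-4.999, STA),
            (0.3, STA),
            (4.999, STA),
            (5.0, IMP),             # bin edge: +5 belongs to improvement
            (12.0, IMP),
        ],
    )
    def test_bins(self, delta, expected):
        assert classify_period_delta(delta) is expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), None])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(DomainError):
            classify_period_delta(bad)

    def test_partition_and_monotonicity(self):
        """Each delta fires exactly one predicate; severity is monotone in delta."""
        rng = np.random.default_rng(42)
        deltas = rng.uniform(-40, 40, size=100_000)
        # independent predicates, evaluated directly from the bin definitions
        fired = (
            (deltas < -10).astype(int)
            + ((deltas >= -10) & (deltas <= -5)).astype(int)
            + ((deltas > -5) & (deltas < 5)).astype(int)
            + (deltas >= 5).astype(int)
        )
        assert (fired == 1).all()
        severity = {SIG: 0, MOD: 1, STA: 2, IMP: 3}
        ranks = np.array([severity[classify_period_delta(d)] for d in np.sort(deltas[:2000])])
        assert (np.diff(ranks) >= 0).all()


class TestCombinedEndpoint:
    @pytest.mark.parametrize(
        "dfvc,ddlco,expected,missing",
        [
            (-11.0, 0.0, True, False),    # FVC arm alone
            (-10.0, 0.0, True, False),    # FVC arm is inclusive at -10
            (-7.0, -16.0, True, False),   # 5-10 point FVC fall + DLCO fall >= 15
            (-7.0, -15.0, True, False),
            (-7.0, -10.0, False, False),
            (-4.0, -30.0, False, False),
            (-7.0, None, False, True),    # indeterminate: DLCO missing
            (-11.0, None, True, False),   # FVC arm does not need DLCO
        ],
    )
    def test_cases(self, dfvc, ddlco, expected, missing):
        result = is_progressive_combined(dfvc, ddlco)
        assert result.progressive is expected
        assert result.dlco_missing is missing
        assert bool(result) is expected

    def test_monotone_in_fvc_severity(self):
        for ddlco in (None, 0.0, -20.0):
            flags = [
                is_progressive_combined(d, ddlco).progressive
                for d in np.linspace(0, -30, 301)
            ]
            # once progressive as FVC decline deepens, always progressive
            assert flags == sorted(flags)


class TestOverallCourse:
    @pytest.mark.parametrize(
        "first,last,expected",
        [
            (90, 68, OverallCategory.MAJOR_DECLINE),        # d = -22
            (90, 70, OverallCategory.SIGNIFICANT_DECLINE),  # d = -20 is significant
            (90, 79, OverallCategory.SIGNIFICANT_DECLINE),
            (90, 80, OverallCategory.MODERATE_DECLINE),     # d = -10
            (90, 85, OverallCategory.MODERATE_DECLINE),     # d = -5
            (90, 88, OverallCategory.STABLE),
            (80, 85, OverallCategory.IMPROVEMENT),          # d = +5
        ],
    )
    def test_bins(self, first, last, expected):
        assert classify_overall_course(first, last) is expected

    def test_partition_of_finite_deltas(self):
        rng = np.random.default_rng(7)
        deltas = rng.uniform(-60, 40, size=100_000)
        fired = (
            (deltas < -20).astype(int)
            + ((deltas >= -20) & (deltas < -10)).astype(int)
            + ((deltas >= -10) & (deltas <= -5)).astype(int)
            + ((deltas > -5) & (deltas < 5)).astype(int)
            + (deltas >= 5).astype(int)
        )
        assert (fired == 1).all()


class TestEpisodeColumn:
    @pytest.mark.parametrize(
        "cats,expected",
        [
            ([STA, STA, IMP], EpisodeColumn.NO_DECLINE),
            ([MOD, STA], EpisodeColumn.ONE_MODERATE),
            ([SIG, STA], EpisodeColumn.ONE_SIGNIFICANT),
            ([MOD, MOD, STA], EpisodeColumn.MULTI_ONLY_MODERATE),
            ([SIG, MOD, STA], EpisodeColumn.MIXED_SIG_AND_MOD),
            ([SIG, SIG, MOD], EpisodeColumn.MIXED_SIG_AND_MOD),
            ([SIG, SIG], EpisodeColumn.MULTI_ONLY_SIGNIFICANT),
        ],
    )
    def test_partition_of_count_pairs(self, cats, expected):
        assert assign_episode_column(cats) is expected

    def test_order_invariant(self):
        cats = [SIG, MOD, STA, IMP, MOD]
        from itertools import permutations

        labels = {assign_episode_column(list(p)) for p in permutations(cats)}
        assert labels == {EpisodeColumn.MIXED_SIG_AND_MOD}

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            assign_episode_column([])


class TestPattern:
    @pytest.mark.parametrize(
        "cats,expected",
        [
            ([SIG, SIG, SIG], PatternLabel.RAPID),
            ([MOD, MOD], PatternLabel.RAPID),
            ([MOD, STA, SIG, STA, STA], PatternLabel.SLOW),
            ([SIG, MOD, STA], PatternLabel.PROGRESSIVE),
            ([MOD, STA], PatternLabel.PROGRESSIVE),   # tie -> progressive
            ([STA, STA], PatternLabel.NON_DECLINING),
            ([STA, IMP, STA], PatternLabel.NON_DECLINING),
        ],
    )
    def test_labels(self, cats, expected):
        assert classify_pattern(cats) is expected

    def test_single_period_rejected(self):
        with pytest.raises(DomainError):
            classify_pattern([SIG])

    def test_rapid_implies_multi_decline_episode_column(self):
        """A rapid pattern can only coexist with a multi-decline episode column."""
        rng = np.random.default_rng(0)
        cats_pool = [SIG, MOD, STA, IMP]
        multi = {
            EpisodeColumn.MULTI_ONLY_MODERATE,
            EpisodeColumn.MIXED_SIG_AND_MOD,
            EpisodeColumn.MULTI_ONLY_SIGNIFICANT,
        }
        for _ in range(500):
            cats = [cats_pool[i] for i in rng.integers(0, 4, size=rng.integers(2, 7))]
            if classify_pattern(cats) is PatternLabel.RAPID:
                assert assign_episode_column(cats) in multi


class TestAggregations:
    def test_period_prevalence_fractions(self):
        patients = [
            make_patient(f"P{i}", [(0, 90), (12, 90 + d)])
            for i, d in enumerate([-18, -18, -18, 0, 0, 0, 0, 0, 0, 12])
        ]
        prevalence = period_prevalence(cohort_periods(Cohort(patients=patients)))
        row = prevalence[prevalence["index_k"] == 1].iloc[0]
        assert row["significant_decline"] == pytest.approx(0.30)
        assert row["improvement"] == pytest.approx(0.10)
        assert sum(row[c.value] for c in PeriodCategory) == pytest.approx(1.0)

    def test_transitions_count_only_consecutive_pairs(self):
        consecutive = make_patient("A", [(0, 90), (12, 78), (24, 78)])   # SIG then STABLE
        gapped = make_patient("B", [(0, 90), (12, 78), (36, 70), (48, 70)])
        matrix = transition_counts(cohort_periods(Cohort(patients=[consecutive, gapped])))
        assert matrix.loc["significant_decline", "stable"] == 1
        # B contributes no (k, k+1) pair around the gap: k=1 and k=4 only...
        assert matrix.to_numpy().sum() == 1

    def test_crosstab_single_patient(self):
        patient = make_patient("P1", [(0, 90), (12, 89), (24, 88)])
        counts, pct = crosstab_overall_by_episode(Cohort(patients=[patient]))
        assert counts.loc["stable", "no_decline"] == 1
        assert pct.loc["stable", "no_decline"] == 100
        assert counts.to_numpy().sum() == 1

    def test_crosstab_conserves_column_totals(self):
        from ildtraj import make_table_fixture
        from ildtraj.reference import CROSSTAB_COUNTS

        cohort = make_table_fixture(CROSSTAB_COUNTS)
        counts, _ = crosstab_overall_by_episode(cohort)
        expected_cols = {
            col.value: sum(CROSSTAB_COUNTS[row][col] for row in CROSSTAB_COUNTS)
            for col in EpisodeColumn
        }
        assert counts.sum(axis=0).to_dict() == expected_cols
        assert counts.to_numpy().sum() == 535

    def test_mortality_summary(self):
        patients = [
            make_patient(f"P{i}", [(0, 90)], died=(i == 0)) for i in range(10)
        ]
        table = mortality_summary(Cohort(patients=patients))
        assert table.iloc[0]["deaths"] == 1 and table.iloc[0]["pct"] == 10

    def test_mortality_empty_group_blank(self):
        table = mortality_summary(Cohort(patients=[]))
        assert len(table) == 0


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.5, 1), (1.5, 2), (2.4, 2), (-0.5, -1), (-1.5, -2), (26.51, 27), (44.38, 44)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_up(x) == expected
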
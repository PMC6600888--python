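"""Concordance statistics and the shortened-Finnish retention grid."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from grogscreen import (
    CohortParams,
    DrinkingOccasion,
    InsufficientDataError,
    TwoByTwo,
    UndefinedStatisticError,
    ValidationError,
    clopper_pearson,
    cross_tabulate,
    exclude_zero_variance,
    generate_cohort,
    pearson_r,
    retention_grid,
    sensitivity_specificity,
)


def occ(days, drinks):
    return DrinkingOccasion(days_before_survey=days, standard_drinks=drinks)


class TestCrossTabulate:
    def test_enumeration(self):
        t = cross_tabulate([True, True, False], [True, False, False])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 0, 1, 1)

    def test_identical_flags_no_disagreement(self):
        t = cross_tabulate([True, False, True], [True, False, True])
        assert t.fn == t.fp == 0

    def test_index_all_positive(self):
        t = cross_tabulate([True] * 4, [True, True, False, False])
        assert t.tn == 0 and t.fp == 2

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            cross_tabulate([True], [True, False])


class TestClopperPearson:
    def test_printed_interval_six_of_nine(self):
        lo, hi = clopper_pearson(6, 9)
        assert round(lo * 100, 1) == 29.9
        assert round(hi * 100, 1) == 92.5

    def test_printed_interval_174_of_175(self):
        lo, hi = clopper_pearson(174, 175)
        assert round(lo * 100, 1) == 96.9
        assert round(hi * 100, 1) == 100.0

    def test_degenerate_bounds(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            clopper_pearson(5, 4)
        with pytest.raises(ValidationError):
            clopper_pearson(0, 0)

    @given(n=st.integers(1, 40), s=st.data())
    def test_point_estimate_inside_interval(self, n, s):
        successes = s.draw(st.integers(0, n))
        lo, hi = clopper_pearson(successes, n)
        assert 0.0 <= lo <= successes / n <= hi <= 1.0


class TestSensitivitySpecificity:
    def test_reconstructed_study_table(self):
        r = sensitivity_specificity(TwoByTwo(tp=174, fn=1, fp=3, tn=6))
        assert r.sensitivity == pytest.approx(174 / 175)
        assert r.specificity == pytest.approx(6 / 9)
        assert round(r.sensitivity * 100) == 99
        assert round(r.specificity * 100) == 67

    def test_perfect_agreement(self):
        r = sensitivity_specificity(TwoByTwo(5, 0, 0, 5))
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_all_missed(self):
        r = sensitivity_specificity(TwoByTwo(0, 5, 0, 5))
        assert r.sensitivity == 0.0 and r.specificity == 1.0

    def test_empty_margin_named(self):
        with pytest.raises(UndefinedStatisticError, match="sensitivity"):
            sensitivity_specificity(TwoByTwo(0, 0, 3, 6))
        with pytest.raises(UndefinedStatisticError, match="specificity"):
            sensitivity_specificity(TwoByTwo(3, 6, 0, 0))

    @given(perm_seed=st.integers(0, 1000))
    def test_invariant_to_participant_order(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        index = rng.random(30) < 0.6
        ref = rng.random(30) < 0.5
        perm = rng.permutation(30)
        a = sensitivity_specificity(cross_tabulate(index, ref))
        b = sensitivity_specificity(cross_tabulate(index[perm], ref[perm]))
        assert a == b


class TestPearson:
    def test_identity_and_sign(self):
        x = [1.0, 2.0, 5.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.982, abs=5e-4)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(seed=st.integers(0, 100))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(25)
        y = x * 2 + rng.random(25)
        assert pearson_r(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, rel=1e-12
        )


def _even_cohort():
    """All occasions equal per person, evenly spaced: every shortened
    estimate is proportional to the full one."""
    rng = np.random.default_rng(5)
    cohort = []
    for _ in range(12):
        q = float(rng.uniform(2, 30))
        gap = int(rng.integers(3, 40))
        cohort.append([occ(gap * (i + 1), q) for i in range(4)])
    return cohort


class TestRetentionGrid:
    def test_full_entry_is_exactly_one(self):
        grid = retention_grid(_even_cohort())
        assert grid.entry(4, 4) == 1.0

    def test_even_cohort_all_entries_one(self):
        grid = retention_grid(_even_cohort())
        assert np.allclose(grid.r_squared, 1.0, atol=1e-12)

    def test_entries_in_unit_interval_on_generated_cohort(self):
        cohort = generate_cohort(CohortParams(n_participants=120), seed=3)
        occasions = [r.occasions for r in cohort if r.is_drinker]
        grid = retention_grid(occasions)
        assert np.all(grid.r_squared >= 0.0) and np.all(grid.r_squared <= 1.0)
        assert grid.n_used + grid.n_excluded == len(occasions)
        # k = 4 rows/columns reuse all the data in that dimension
        assert grid.entry(4, 4) == 1.0

    def test_too_few_eligible(self):
        with pytest.raises(InsufficientDataError):
            retention_grid([[occ(3, 5)]] * 10)

    def test_unknown_variable(self):
        with pytest.raises(ValidationError):
            retention_grid(_even_cohort(), variable="nonsense")

    def test_drinks_per_occasion_variable_ignores_frequency_axis(self):
        cohort = generate_cohort(CohortParams(n_participants=120), seed=3)
        occasions = [r.occasions for r in cohort if r.is_drinker]
        grid = retention_grid(occasions, variable="drinks_per_occasion")
        for kq in range(1, 5):
            row = [grid.entry(kq, kf) for kf in range(1, 5)]
            assert max(row) - min(row) <= 1e-12 or kq == 4


class TestExcludeZeroVariance:
    def test_constant_dropped(self):
        cohort = [
            [occ(7 * (i + 1), 12) for i in range(4)],
            [occ(7 * (i + 1), q) for i, q in enumerate([12, 12, 12, 11])],
        ]
        kept, dropped = exclude_zero_variance(cohort)
        assert dropped == 1 and len(kept) == 1

    def test_empty_cohort(self):
        assert exclude_zero_variance([]) == ([], 0)

    def test_short_records_kept(self):
        kept, dropped = exclude_zero_variance([[occ(3, 5), occ(9, 5)]])
        assert dropped == 0 and len(kept) == 1
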
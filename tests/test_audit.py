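"""Modified AUDIT-C scoring, midpoints and subset risk rules."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from grogscreen import (
    DAYS_PER_MONTH,
    FrequencyCategory,
    ValidationError,
    audit3_risk,
    audit12_risk,
    derive_audit2m,
    frequency_midpoint_per_day,
    occasions_per_week_to_per_day,
    quantity_midpoint,
    score_audit1m,
    score_audit3mv,
    total_audit_cm,
)

C = FrequencyCategory


class TestDeriveAudit2m:
    @pytest.mark.parametrize(
        "drinks, score",
        [
            (12, 4), (1, 0), (2, 0), (3, 1), (4, 1), (5, 2), (6, 2),
            (7, 3), (9, 3), (10, 4), (0, 0),
            # gap values resolve by round-half-up to integer drinks
            (4.5, 2), (2.5, 1), (9.5, 4), (2.4, 0),
        ],
    )
    def test_recoding(self, drinks, score):
        assert derive_audit2m(drinks) == score

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            derive_audit2m(-1)

    @given(x=st.floats(0, 100), y=st.floats(0, 100))
    def test_step_function_monotone(self, x, y):
        lo, hi = sorted([x, y])
        assert derive_audit2m(lo) <= derive_audit2m(hi)
        assert derive_audit2m(x) in {0, 1, 2, 3, 4}

    def test_image_is_all_five_scores(self):
        assert {derive_audit2m(d) for d in range(0, 15)} == {0, 1, 2, 3, 4}


class TestItemScores:
    def test_ordinal_positions(self):
        assert score_audit1m(C.MONTHLY_1_3) == 2
        assert score_audit1m(C.MOST_DAYS) == 4
        assert score_audit3mv(C.NEVER) == 0

    def test_never_invalid_for_drinker_audit1m(self):
        with pytest.raises(ValidationError):
            score_audit1m(C.NEVER)
        # ... but fine when the respondent is not a confirmed drinker
        assert score_audit1m(C.NEVER, past_year_drinker=False) == 0


class TestTotal:
    def test_male_at_risk(self):
        r = total_audit_cm(1, 4, 2, "male")
        assert r.total == 7 and r.at_risk

    def test_female_below_threshold(self):
        assert not total_audit_cm(1, 1, 0, "female").at_risk

    def test_sex_specific_threshold(self):
        assert total_audit_cm(1, 1, 1, "female").at_risk
        assert not total_audit_cm(1, 1, 1, "male").at_risk

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            total_audit_cm(1, 5, 1, "male")
        with pytest.raises(ValidationError):
            total_audit_cm(1, 1, 1, "other")

    @given(
        scores=st.tuples(*[st.integers(0, 4)] * 3).filter(lambda s: sum(s) < 12)
    )
    def test_woman_at_risk_implies_man_one_higher(self, scores):
        a, b, c = scores
        if total_audit_cm(a, b, c, "female").at_risk:
            bumped = [a, b, c]
            for i in range(3):
                if bumped[i] < 4:
                    bumped[i] += 1
                    break
            assert total_audit_cm(*bumped, "male").at_risk


class TestMidpoints:
    def test_weekly_anchor(self):
        assert round(occasions_per_week_to_per_day(1.0), 2) == 0.14

    @pytest.mark.parametrize(
        "category, per_day",
        [
            (C.NEVER, 0.0),
            (C.LT_MONTHLY, 0.5 / DAYS_PER_MONTH),
            (C.MONTHLY_1_3, 2.0 / DAYS_PER_MONTH),
            (C.WEEKLY_1_3, 2.0 / 7.0),
            (C.MOST_DAYS, 5.5 / 7.0),
        ],
    )
    def test_frequency_midpoints(self, category, per_day):
        assert frequency_midpoint_per_day(category) == pytest.approx(per_day)

    @pytest.mark.parametrize(
        "score, drinks", [(0, 1.5), (1, 3.5), (2, 5.5), (3, 8.0), (4, 10.0)]
    )
    def test_quantity_midpoints(self, score, drinks):
        assert quantity_midpoint(score) == drinks

    def test_out_of_range_score(self):
        with pytest.raises(ValidationError):
            quantity_midpoint(5)


class TestSubsetRisk:
    @pytest.mark.parametrize(
        "category, score, short, long",
        [
            (C.WEEKLY_1_3, 4, True, True),  # 2/7 x 10 = 2.857 > 2
            (C.LT_MONTHLY, 4, True, False),  # 0.0164 x 10 = 0.164
            (C.MOST_DAYS, 0, False, False),  # 1.5 <= 4; 0.786 x 1.5 = 1.18
        ],
    )
    def test_audit12(self, category, score, short, long):
        r = audit12_risk(category, score)
        assert (r.short_term, r.long_term) == (short, long)
        assert r.any_risk == (short or long)

    def test_audit12_monthly_switch(self):
        # with the stricter switch, less-than-monthly drinkers are not
        # short-term flagged even at the top quantity category
        r = audit12_risk(C.LT_MONTHLY, 4, short_term_min_frequency="monthly")
        assert not r.short_term
        assert audit12_risk(C.MONTHLY_1_3, 4, short_term_min_frequency="monthly").short_term

    @pytest.mark.parametrize(
        "category, short, long",
        [
            (C.NEVER, False, False),
            (C.WEEKLY_1_3, True, False),  # 5 x 0.2857 = 1.43 <= 2
            (C.MOST_DAYS, True, True),  # 5 x 0.786 = 3.93 > 2
        ],
    )
    def test_audit3(self, category, short, long):
        r = audit3_risk(category)
        assert (r.short_term, r.long_term) == (short, long)

    def test_audit3_long_term_iff_most_days(self):
        for category in C:
            assert audit3_risk(category).long_term == (category is C.MOST_DAYS)

    @given(
        cat=st.sampled_from([C.LT_MONTHLY, C.MONTHLY_1_3, C.WEEKLY_1_3]),
        score=st.integers(0, 3),
    )
    def test_monotone_in_both_items(self, cat, score):
        base = audit12_risk(cat, score)
        up_cat = audit12_risk(C(int(cat) + 1), score)
        up_score = audit12_risk(cat, score + 1)
        for before, after in [(base, up_cat), (base, up_score)]:
            assert after.short_term >= before.short_term
            assert after.long_term >= before.long_term
        assert audit3_risk(C(int(cat) + 1)).short_term >= audit3_risk(cat).short_term
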
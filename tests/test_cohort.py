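"""Synthetic-cohort generator: determinism, structure and marginals."""

import numpy as np
import pytest

from grogscreen import (
    CohortParams,
    FrequencyCategory,
    ValidationError,
    generate_cohort,
    generate_occasions,
    past_year_occasions,
    report_categories,
)

C = FrequencyCategory


class TestDeterminism:
    def test_same_seed_identical(self):
        params = CohortParams(n_participants=40)
        assert generate_cohort(params, 123) == generate_cohort(params, 123)

    def test_different_seed_differs(self):
        params = CohortParams(n_participants=40)
        assert generate_cohort(params, 1) != generate_cohort(params, 2)


class TestStructure:
    def test_counts_and_gates(self, small_cohort):
        assert len(small_cohort) == 60
        for r in small_cohort:
            if r.is_drinker:
                assert r.occasions, "drinkers must have at least one occasion"
                assert past_year_occasions(r.occasions), "occasion within window"
                assert r.audit1m is not None and r.audit1m != C.NEVER
                assert r.audit3mv is not None
            else:
                assert r.occasions == ()
                assert r.prep_drank is False and r.check_drank is False
                assert all(d is C.NEVER for d in r.dependence_ratings)

    def test_occasions_sorted_most_recent_first(self, small_cohort):
        for r in small_cohort:
            days = [o.days_before_survey for o in r.occasions]
            assert days == sorted(days)

    def test_no_non_drinkers_when_proportion_zero(self):
        cohort = generate_cohort(
            CohortParams(n_participants=50, prop_non_drinker=0.0), seed=4
        )
        assert all(r.is_drinker for r in cohort)

    def test_dependence_strata_label_consistent(self, small_cohort):
        from grogscreen import DependenceStatus, dependence_status

        labels = {
            dependence_status(r.dependence_ratings)
            for r in small_cohort
            if r.is_drinker
        }
        assert labels == {DependenceStatus.DEPENDENT, DependenceStatus.NON_DEPENDENT}

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            CohortParams(n_participants=0)
        with pytest.raises(ValidationError):
            CohortParams(prop_non_drinker=1.5)
        with pytest.raises(ValidationError):
            CohortParams(frequency_class_probs=(0.5, 0.5, 0.5, 0.5))


class TestOccasionProcess:
    def test_expected_count_for_twice_monthly_rate(self):
        rng = np.random.default_rng(0)
        rate = 2.0 / 30.4375  # two occasions a month
        occasions = generate_occasions(rng, rate, person_median=16.0, sigma_within=0.0)
        assert 12 <= len(occasions) <= 36  # ~24 expected, +/- 50%

    def test_degenerate_quantity_distribution(self):
        rng = np.random.default_rng(1)
        occasions = generate_occasions(rng, 0.1, person_median=16.0, sigma_within=0.0)
        assert all(o.standard_drinks == 16.0 for o in occasions)

    def test_low_rate_still_yields_an_occasion(self):
        rng = np.random.default_rng(2)
        occasions = generate_occasions(
            rng, 4.0 / 366.0, person_median=16.0, sigma_within=0.0
        )
        assert len(occasions) >= 1
        assert all(o.days_before_survey <= 366 for o in occasions)

    def test_copy_probability_one_repeats_first_quantity(self):
        rng = np.random.default_rng(3)
        occasions = generate_occasions(
            rng, 0.1, 16.0, sigma_within=0.5, copy_last_quantity_prob=1.0
        )
        quantities = {o.standard_drinks for o in occasions}
        assert len(quantities) == 1


class TestReportedCategories:
    def test_noise_free_binning(self):
        rng = np.random.default_rng(0)
        occasions = generate_occasions(rng, 2.0 / 30.4375, 16.0, 0.0)
        audit1m, _ = report_categories(rng, 2.0 / 30.4375, occasions, noise=0.0)
        assert audit1m is C.MONTHLY_1_3

    def test_light_drinker_never_heavy(self):
        rng = np.random.default_rng(0)
        occasions = generate_occasions(rng, 0.1, person_median=2.0, sigma_within=0.0)
        _, audit3mv = report_categories(rng, 0.1, occasions, noise=0.0)
        assert audit3mv is C.NEVER

    def test_full_noise_moves_exactly_one_level(self):
        rng = np.random.default_rng(0)
        occasions = generate_occasions(rng, 1.0 / 7.0, 16.0, 0.0)
        for _ in range(20):
            audit1m, audit3mv = report_categories(rng, 1.0 / 7.0, occasions, noise=1.0)
            truth1m, truth3 = report_categories(rng, 1.0 / 7.0, occasions, noise=0.0)
            assert abs(int(audit1m) - int(truth1m)) <= 1
            assert audit1m != C.NEVER


class TestMarginals:
    """Light-weight distribution checks; the full calibration-recovery
    checks at n = 5000 live in the acceptance suite."""

    def test_drinker_fraction(self):
        cohort = generate_cohort(CohortParams(n_participants=2000), seed=9)
        frac = sum(r.is_drinker for r in cohort) / len(cohort)
        assert frac == pytest.approx(0.8, abs=0.03)

    def test_frequency_class_marginals(self):
        cohort = generate_cohort(
            CohortParams(n_participants=3000, prop_non_drinker=0.0), seed=9
        )
        counts = np.zeros(5)
        for r in cohort:
            counts[int(r.audit1m)] += 1
        shares = counts / counts.sum()
        assert shares[0] == 0.0  # drinkers never report NEVER
        for share, target in zip(shares[1:], (0.304, 0.424, 0.261, 0.011)):
            assert share == pytest.approx(target, abs=0.025)

    def test_long_term_risk_share(self):
        from grogscreen import nhmrc_risk_from_summary, summarize

        cohort = generate_cohort(
            CohortParams(n_participants=3000, prop_non_drinker=0.0), seed=9
        )
        flags = [
            nhmrc_risk_from_summary(summarize(r.occasions)).long_term
            for r in cohort
        ]
        assert np.mean(flags) * 100 == pytest.approx(44.0, abs=5.0)
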
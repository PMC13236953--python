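"""Life-table conversion, field calibration and treatment transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiteflypop import (
    DailyRates,
    DomainError,
    InconsistentLifeTableError,
    InfeasibleTargetError,
    TreatmentSpec,
    aggregate_nymph,
    apply_treatment,
    calibrate_field_adjustment,
    daily_development_rate,
    daily_mortality_rate,
    emergence_probability,
    generation_time,
    simulate_cohort,
    with_field_adjustment,
)


@pytest.mark.parametrize("m, expected", [(1.0, 1.0), (10.0, 0.1), (16.0, 0.0625)])
def test_daily_development_rate_is_reciprocal_duration(m, expected):
    assert daily_development_rate(m) == expected


def test_daily_development_rate_rejects_subday_duration():
    with pytest.raises(DomainError):
        daily_development_rate(0.5)


@pytest.mark.parametrize("survival, expected", [(1.0, 0.0), (0.9, 0.1), (0.85, 0.15)])
def test_daily_mortality_is_survival_complement(survival, expected):
    assert daily_mortality_rate(survival) == pytest.approx(expected)


@pytest.mark.parametrize("survival", [0.0, -0.1, 1.5])
def test_daily_mortality_rejects_invalid_survival(survival):
    with pytest.raises(DomainError):
        daily_mortality_rate(survival)


class TestNymphAggregation:
    def test_zero_mortality_case(self):
        r2, d2, s2 = aggregate_nymph((5, 4, 3, 4), (0, 0, 0, 0))
        assert (r2, d2, s2) == (0.0625, 0.0, 0.9375)

    def test_duration_weighted_mortality(self):
        r2, d2, s2 = aggregate_nymph((5, 4, 3, 4), (0.1, 0.1, 0.2, 0.2))
        assert r2 == 0.0625
        assert d2 == pytest.approx(0.14375)
        assert s2 == pytest.approx(0.79375)

    def test_rejects_rates_summing_above_one(self):
        with pytest.raises(InconsistentLifeTableError):
            aggregate_nymph((1, 1, 1, 1), (0.9, 0.9, 0.9, 0.9))


class TestEmergence:
    def test_certain_without_mortality(self):
        r = DailyRates(28.0, 0.1, 0.0, 0.0625, 0.0, 0.2, 0.0, 0.05, 5.0)
        assert emergence_probability(r) == 1.0

    def test_worked_example(self, worked_rates):
        # (0.1/0.15) * (0.0625/0.20625) * (0.2/0.25)
        assert emergence_probability(worked_rates) == pytest.approx(0.161616, abs=1e-5)

    def test_monte_carlo_cohort_agrees(self, worked_rates):
        n = 100_000
        p = emergence_probability(worked_rates)
        phat = simulate_cohort(worked_rates, n=n, seed=11)
        assert abs(phat - p) < 3.0 * math.sqrt(p * (1 - p) / n)


class TestFieldCalibration:
    def test_fixed_point_at_baseline(self, worked_rates):
        q = calibrate_field_adjustment(worked_rates, emergence_probability(worked_rates))
        assert q == 0.0

    def test_worked_example_value(self, worked_rates):
        q = calibrate_field_adjustment(worked_rates, 0.10)
        assert q == pytest.approx(0.034, abs=2e-3)

    def test_round_trip_to_target(self, worked_rates, rates28):
        for rates in (worked_rates, rates28):
            q = calibrate_field_adjustment(rates, 0.10)
            adjusted = with_field_adjustment(rates, q)
            assert emergence_probability(adjusted) == pytest.approx(0.10, abs=1e-6)

    def test_infeasible_target_above_baseline(self, worked_rates):
        with pytest.raises(InfeasibleTargetError):
            calibrate_field_adjustment(worked_rates, 0.5)


class TestTreatment:
    def test_zero_kill_is_identity(self, worked_rates):
        assert apply_treatment(worked_rates, TreatmentSpec(0.0, 0.0, 20)) == worked_rates

    def test_total_adult_kill_zeroes_daily_survival(self, worked_rates):
        treated = apply_treatment(worked_rates, TreatmentSpec(1.0, 0.0, 20))
        assert treated.d_adult == 1.0

    def test_daily_increment_compounds_to_generation_kill(self, worked_rates):
        treated = apply_treatment(worked_rates, TreatmentSpec(0.6, 0.0, 20))
        extra = treated.d_adult - worked_rates.d_adult
        assert extra == pytest.approx(0.04478, abs=1e-4)
        assert (1.0 - extra) ** 20 == pytest.approx(0.4, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0),
        pl=st.floats(0.0, 1.0),
    )
    def test_monotone_in_kill_fractions(self, p1, p2, pl):
        base = DailyRates(28.0, 0.1, 0.05, 0.0625, 0.14375, 0.2, 0.05, 0.05, 5.0)
        lo, hi = sorted((p1, p2))
        t_lo = apply_treatment(base, TreatmentSpec(lo, pl, 20))
        t_hi = apply_treatment(base, TreatmentSpec(hi, pl, 20))
        assert t_hi.d_adult >= t_lo.d_adult
        n_lo = apply_treatment(base, TreatmentSpec(pl, lo, 20))
        n_hi = apply_treatment(base, TreatmentSpec(pl, hi, 20))
        assert n_hi.d_nymph >= n_lo.d_nymph


class TestGenerationTime:
    def test_sums_expected_stage_durations(self, worked_rates):
        assert generation_time(worked_rates) == 31  # 10 + 16 + 5

    def test_unit_rates_give_three_days(self):
        r = DailyRates(28.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.05, 5.0)
        assert generation_time(r) == 3

    def test_default_fixture_is_about_twenty_days(self, rates28):
        assert 18 <= generation_time(rates28) <= 22


@settings(derandomize=True, max_examples=100)
@given(
    r=st.floats(0.01, 0.6), d=st.floats(0.0, 0.39),
    r2=st.floats(0.01, 0.6), d2=st.floats(0.0, 0.39),
)
def test_stay_probabilities_complement_exactly(r, d, r2, d2):
    """r + d + s == 1 holds exactly in floating point for every stage."""
    rates = DailyRates(28.0, r, d, r2, d2, r, d, 0.05, 1.0)
    assert (rates.r_egg + rates.d_egg) + rates.s_egg == 1.0
    assert (rates.r_nymph + rates.d_nymph) + rates.s_nymph == 1.0
    assert (rates.r_pupa + rates.d_pupa) + rates.s_pupa == 1.0
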
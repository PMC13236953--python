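"""Projection-matrix assembly, interpolation and single-population dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from whiteflypop import (
    DailyRates,
    InfeasibleCalibrationError,
    InputLengthError,
    ModelParams,
    build_matrix,
    calibrate_density_dependence,
    emergence_probability,
    interpolate_matrix,
    simulate,
    step,
)


def _rates(T=28.0, **kw):
    base = dict(r_egg=0.1, d_egg=0.05, r_nymph=0.0625, d_nymph=0.14375,
                r_pupa=0.2, d_pupa=0.05, d_adult=0.05, fecundity=5.0)
    base.update(kw)
    return DailyRates(temperature=T, **base)


class TestBuildMatrix:
    def test_entries_match_daily_rates(self, worked_rates):
        M = build_matrix(worked_rates).values
        assert M[0, 0] == worked_rates.s_egg
        assert M[1, 0] == 0.1
        assert M[1, 1] == worked_rates.s_nymph
        assert M[2, 1] == 0.0625
        assert M[2, 2] == worked_rates.s_pupa
        assert M[3, 2] == 0.2
        assert M[3, 3] == 0.95
        assert M[0, 3] == 5.0
        # everything else zero
        mask = np.ones((4, 4), dtype=bool)
        for ij in [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2), (3, 3), (0, 3)]:
            mask[ij] = False
        assert np.all(M[mask] == 0.0)

    def test_frozen_stages_give_identity_fixed_point(self):
        r = _rates(r_egg=0, d_egg=0, r_nymph=0, d_nymph=0, r_pupa=0, d_pupa=0,
                   d_adult=0, fecundity=0)
        M = build_matrix(r)
        assert np.array_equal(M.values, np.eye(4))
        state = np.array([3.0, 2.0, 1.0, 5.0])
        assert np.array_equal(step(state, M, 0.0), state)

    def test_no_reproduction_decays_to_zero(self):
        r = _rates(fecundity=0.0)
        M = build_matrix(r)
        state = np.array([100.0, 100.0, 100.0, 100.0])
        totals = []
        for _ in range(300):
            new = step(state, M, 0.0)
            totals.append(new.sum())
            assert new.sum() <= state.sum() + 1e-12
            state = new
        assert totals[-1] < 1e-2


class TestInterpolation:
    @pytest.fixture()
    def anchors(self):
        return [build_matrix(_rates(T=T, fecundity=T / 4.0)) for T in (16, 20, 24, 28, 32)]

    def test_exact_at_anchor(self, anchors):
        assert np.array_equal(interpolate_matrix(anchors, 24.0).values, anchors[2].values)

    def test_midpoint_is_elementwise_average(self, anchors):
        M = interpolate_matrix(anchors, 26.0).values
        expected = 0.5 * anchors[2].values + 0.5 * anchors[3].values
        assert np.array_equal(M, expected)

    def test_clamps_outside_anchor_range(self, anchors):
        assert np.array_equal(interpolate_matrix(anchors, 33.0).values, anchors[-1].values)
        assert np.array_equal(interpolate_matrix(anchors, 10.0).values, anchors[0].values)

    def test_continuous_in_temperature(self, anchors):
        for T in np.linspace(16, 32, 33):
            a = interpolate_matrix(anchors, T).values
            b = interpolate_matrix(anchors, T + 1e-9).values
            assert np.max(np.abs(a - b)) < 1e-6


class TestStep:
    def test_zero_state_is_absorbing(self, worked_rates):
        M = build_matrix(worked_rates)
        assert np.array_equal(step(np.zeros(4), M, 0.01), np.zeros(4))

    def test_without_density_dependence_is_pure_projection(self, worked_rates):
        M = build_matrix(worked_rates)
        state = np.array([10.0, 5.0, 2.0, 1.0])
        assert np.array_equal(step(state, M, 0.0), M.values @ state)

    def test_density_subtraction_forced_arithmetic(self):
        # adult survival 1, no flows: adults stay 100 after multiplication
        r = _rates(r_egg=0, d_egg=0, r_nymph=0, d_nymph=0, r_pupa=0, d_pupa=0,
                   d_adult=0, fecundity=0)
        state = np.array([0.0, 0.0, 0.0, 100.0])
        out = step(state, build_matrix(r), 0.001)
        assert out[3] == pytest.approx(90.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        e=st.floats(0, 1e4), n=st.floats(0, 1e4), p=st.floats(0, 1e4),
        a=st.floats(0, 1e4), gamma=st.floats(0, 1.0),
    )
    def test_never_negative(self, e, n, p, a, gamma):
        base = DailyRates(28.0, 0.1, 0.05, 0.0625, 0.14375, 0.2, 0.05, 0.05, 5.0)
        out = step(np.array([e, n, p, a]), build_matrix(base), gamma)
        assert np.all(out >= 0.0)


class TestSimulate:
    def test_zero_horizon_returns_initial_state(self, fitted):
        params = ModelParams(anchor_rates=fitted.anchor_rates(), gamma=fitted.gamma_,
                             horizon=0)
        traj = simulate(params, np.full(10, 28.0))
        assert len(traj) == 1
        assert tuple(traj[["eggs", "nymphs", "pupae", "adults"]].iloc[0]) == params.initial_state

    def test_horizon_longer_than_series_rejected(self, fitted):
        with pytest.raises(InputLengthError):
            simulate(fitted.params_, np.full(10, 28.0))

    def test_null_treatment_identical_to_wild_type(self, fitted, constant_28):
        wt = simulate(fitted.params_, constant_28)
        null = simulate(fitted.params_, constant_28, fitted.treatment(0.0, 0.0))
        assert wt.equals(null)

    def test_steady_state_matches_scalar_equilibrium_oracle(self, fitted, constant_28):
        """Long-run adults at constant 28 degC solve the one-day fixed point.

        With the daily order multiply-then-subtract, the equilibrium A*
        satisfies A = B - gamma*B^2 with B = (1 - d_A + F*E) * A, where E
        is the egg-to-adult emergence probability.  Solved here by an
        independent brute-force root-find on that scalar equation.
        """
        r = fitted.anchor_rates()[3]
        assert r.temperature == 28.0
        growth = 1.0 - r.d_adult + r.fecundity * emergence_probability(r)
        gamma = fitted.gamma_

        def gap(A):
            B = growth * A
            return (B - gamma * B * B) - A

        a_star = brentq(gap, 1.0, 1e6, xtol=1e-9)
        traj = simulate(fitted.params_, constant_28)
        steady = traj["adults"].to_numpy()[-60:].mean()
        assert steady == pytest.approx(a_star, rel=0.01)
        assert steady == pytest.approx(fitted.model.carrying_capacity, rel=0.01)


class TestDensityCalibration:
    def test_contract_and_monotonicity(self, fitted, constant_28):
        r = fitted.anchor_rates()[3]
        gamma = fitted.gamma_
        params = fitted.params_

        def steady(g):
            import dataclasses
            p = dataclasses.replace(params, gamma=g)
            return simulate(p, constant_28)["adults"].to_numpy()[-60:].mean()

        assert steady(gamma) == pytest.approx(500.0, abs=5.0)
        assert steady(2 * gamma) < steady(gamma)

    def test_smaller_capacity_needs_larger_gamma(self, fitted):
        r = fitted.anchor_rates()[3]
        g500 = calibrate_density_dependence(r, 500.0)
        g250 = calibrate_density_dependence(r, 250.0)
        assert g250 > g500

    def test_non_growing_population_is_infeasible(self):
        shrinking = _rates(fecundity=0.01, d_adult=0.5)
        with pytest.raises(InfeasibleCalibrationError):
            calibrate_density_dependence(shrinking, 500.0)
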
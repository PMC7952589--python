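"""Piecewise-exponential HIF-α relaxation and the cycle-averaged payoff."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifcycle import (
    FacultativeStrategy,
    ModelParameters,
    PeriodicSchedule,
    closed_form_cycle_payoff,
    cycle_steady_state,
    expected_payoff,
    numeric_payoff,
    perfect_strategy_payoff,
    periodic_profile,
    segment_u,
    simulate_trajectory,
)
from hifcycle.environment import HYPOXIA, NORMOXIA, constant_profile

TABLE_STRATEGY = FacultativeStrategy(0.540, 1.0)


def quadrature_payoff(schedule, strategy, params, dt=0.001):
    """Independent oracle: trapezoidal integration along the steady-state cycle."""
    u0, _ = cycle_steady_state(schedule, strategy)
    profile = periodic_profile(schedule, n_cycles=1, dt=dt)
    trajectory = simulate_trajectory(profile, strategy, u0=u0, params=params)
    return numeric_payoff(trajectory, params)


class TestSegmentRelaxation:
    def test_zero_duration_is_identity(self):
        assert segment_u(0.3, HYPOXIA, 0.0, TABLE_STRATEGY) == 0.3

    def test_target_is_fixed_point(self):
        s = TABLE_STRATEGY
        assert segment_u(s.u_max, HYPOXIA, 500.0, s) == pytest.approx(s.u_max)
        assert segment_u(s.u_min, NORMOXIA, 500.0, s) == pytest.approx(s.u_min)

    def test_ninety_percent_rise_in_60_min(self):
        """alpha0 = ln(10)/60 drives u from 0 to 0.9 in exactly one hour."""
        strat = FacultativeStrategy(0.0, 1.0, alpha0=np.log(10) / 60, alpha1=1.0)
        assert segment_u(0.0, HYPOXIA, 60.0, strat) == pytest.approx(0.9, abs=1e-12)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            segment_u(0.5, HYPOXIA, -1.0, TABLE_STRATEGY)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        u_start=st.floats(0, 1),
        state=st.sampled_from([HYPOXIA, NORMOXIA]),
        a=st.floats(0, 200),
        b=st.floats(0, 200),
        u_min=st.floats(0, 0.5),
        u_max=st.floats(0.5, 1),
        alpha0=st.floats(1e-4, 1.0),
        alpha1=st.floats(1e-4, 1.0),
    )
    def test_semigroup(self, u_start, state, a, b, u_min, u_max, alpha0, alpha1):
        """Relaxing a+b minutes equals relaxing a minutes then b minutes."""
        strat = FacultativeStrategy(u_min, u_max, alpha0, alpha1)
        direct = segment_u(u_start, state, a + b, strat)
        stepped = segment_u(segment_u(u_start, state, a, strat), state, b, strat)
        assert direct == pytest.approx(stepped, abs=1e-12)


class TestTrajectories:
    def test_monotone_decay_under_constant_normoxia(self):
        profile = constant_profile(NORMOXIA, 200)
        trajectory = simulate_trajectory(profile, TABLE_STRATEGY, u0=0.9)
        assert np.all(np.diff(trajectory.u_values) < 0)
        assert trajectory.u_values[-1] > TABLE_STRATEGY.u_min

    def test_bounded_between_u0_and_targets(self):
        strat = FacultativeStrategy(0.2, 0.8)
        profile = periodic_profile(PeriodicSchedule(15, 35), n_cycles=20)
        for u0 in (0.05, 0.5, 0.95):
            trajectory = simulate_trajectory(profile, strat, u0=u0)
            lo = min(u0, strat.u_min)
            hi = max(u0, strat.u_max)
            assert trajectory.u_values.min() >= lo - 1e-12
            assert trajectory.u_values.max() <= hi + 1e-12

    def test_degenerate_strategy_constant(self):
        strat = FacultativeStrategy(0.4, 0.4)
        profile = periodic_profile(PeriodicSchedule(10, 10), n_cycles=5)
        trajectory = simulate_trajectory(profile, strat, u0=0.4)
        assert np.allclose(trajectory.u_values, 0.4)

    def test_contraction_to_periodic_orbit(self):
        """Per-cycle endpoint change shrinks below 1e-9 after enough cycles."""
        schedule = PeriodicSchedule(10, 10)
        profile = periodic_profile(schedule, n_cycles=60)
        trajectory = simulate_trajectory(profile, TABLE_STRATEGY, u0=0.1)
        cycle = int(schedule.cycle_length)  # dt=1 → samples per cycle
        endpoints = trajectory.u_values[::cycle]
        assert abs(endpoints[-1] - endpoints[-2]) < 1e-9

    def test_default_initial_u_halfway_rule(self, params):
        profile = periodic_profile(PeriodicSchedule(10, 10), n_cycles=1)
        trajectory = simulate_trajectory(profile, TABLE_STRATEGY, params=params)
        from hifcycle.core import optimal_constitutive_u

        expected = 0.5 * (optimal_constitutive_u(0.5, params) + TABLE_STRATEGY.u_max)
        assert trajectory.u_values[0] == pytest.approx(expected)


class TestSteadyState:
    def test_saturation_limit(self):
        strat = FacultativeStrategy(0.1, 0.9, alpha0=5.0, alpha1=0.0462)
        u_start, _ = cycle_steady_state(PeriodicSchedule(10, 50), strat)
        assert u_start == pytest.approx(strat.u_max, abs=1e-6)

    def test_degenerate_strategy(self):
        strat = FacultativeStrategy(0.3, 0.3)
        assert cycle_steady_state(PeriodicSchedule(10, 10), strat) == pytest.approx(
            (0.3, 0.3)
        )

    def test_matches_long_simulation(self):
        """The 2x2 fixed point equals trajectory endpoints after 200 cycles."""
        schedule = PeriodicSchedule(10, 10)
        profile = periodic_profile(schedule, n_cycles=200)
        trajectory = simulate_trajectory(profile, TABLE_STRATEGY, u0=0.77)
        u_start, u_end = cycle_steady_state(schedule, TABLE_STRATEGY)
        cycle = int(schedule.cycle_length)
        assert trajectory.u_values[-1] == pytest.approx(u_start, abs=1e-8)
        assert trajectory.u_values[-1 - int(schedule.t_h)] == pytest.approx(
            u_end, abs=1e-8
        )

    def test_within_bounds(self):
        for t_n, t_h in [(5, 200), (200, 5), (60, 60)]:
            u_start, u_end = cycle_steady_state(
                PeriodicSchedule(t_n, t_h), TABLE_STRATEGY
            )
            for val in (u_start, u_end):
                assert TABLE_STRATEGY.u_min <= val <= TABLE_STRATEGY.u_max


class TestCyclePayoff:
    def test_degenerate_equals_constitutive(self, params):
        """u_min = u_max reduces the cycle payoff to the static expected payoff."""
        schedule = PeriodicSchedule(30, 70)
        for v in (0.0, 0.37, 1.0):
            strat = FacultativeStrategy(v, v)
            assert closed_form_cycle_payoff(schedule, strat, params) == pytest.approx(
                expected_payoff(v, schedule.q, params), rel=1e-12
            )

    def test_against_dense_quadrature(self, params):
        schedule = PeriodicSchedule(10, 10)
        closed = closed_form_cycle_payoff(schedule, TABLE_STRATEGY, params)
        numeric = quadrature_payoff(schedule, TABLE_STRATEGY, params, dt=0.001)
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_random_sweep_against_quadrature(self, params, rng):
        """Closed form vs trapezoid at dt=0.01 across random schedule/strategy pairs."""
        for _ in range(25):
            t_n, t_h = rng.uniform(2, 200, size=2)
            lo, hi = np.sort(rng.uniform(0, 1, size=2))
            strat = FacultativeStrategy(
                lo, max(hi, lo + 1e-3),
                alpha0=rng.uniform(1e-3, 0.2), alpha1=rng.uniform(1e-3, 0.2),
            )
            schedule = PeriodicSchedule(t_n, t_h)
            closed = closed_form_cycle_payoff(schedule, strat, params)
            numeric = quadrature_payoff(schedule, strat, params, dt=0.01)
            assert closed == pytest.approx(numeric, rel=1e-6)

    def test_instantaneous_limit_is_perfect_strategy(self, params):
        """Very fast relaxation with full range approaches the perfect payoff."""
        schedule = PeriodicSchedule(10, 10)
        strat = FacultativeStrategy(0.0, 1.0, alpha0=1e3, alpha1=1e3)
        fast = closed_form_cycle_payoff(schedule, strat, params)
        perfect = perfect_strategy_payoff(schedule.q, params)
        assert fast == pytest.approx(perfect, rel=1e-3)

    def test_down_regulation_four_times_faster(self):
        strat = FacultativeStrategy(0.0, 1.0)
        # half-life ratio: normoxic relaxation is 4x faster than hypoxic
        assert strat.alpha1 / strat.alpha0 == pytest.approx(4.0, rel=1e-10)


class TestNumericPayoff:
    def test_constant_u_pure_normoxia(self, params):
        profile = constant_profile(NORMOXIA, 100)
        strat = FacultativeStrategy(0.0, 0.0)
        trajectory = simulate_trajectory(profile, strat, u0=0.0)
        assert numeric_payoff(trajectory, params) == pytest.approx(params.r)

    def test_constant_u_pure_hypoxia(self, params):
        profile = constant_profile(HYPOXIA, 100)
        strat = FacultativeStrategy(0.0, 0.0)
        trajectory = simulate_trajectory(profile, strat, u0=0.0)
        assert numeric_payoff(trajectory, params) == pytest.approx(
            params.r - params.m / params.k
        )


def test_invalid_strategy_rejected():
    with pytest.raises(ValueError):
        FacultativeStrategy(0.8, 0.2)
    with pytest.raises(ValueError):
        FacultativeStrategy(0.1, 0.9, alpha0=0.0)
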
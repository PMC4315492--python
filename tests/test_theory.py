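"""Closed-form theory of the LIF + depressing-synapse response."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikelock import (
    NeuronState,
    TMLIFParams,
    closed_form_rate,
    critical_frequencies,
    event_map_step,
    potential_after_n,
    resource_fixed_point,
    spikes_to_threshold,
    theory_curve,
    theory_result,
)

from conftest import iterate_to_threshold, ode_event_map_oracle

valid_params = st.builds(
    TMLIFParams,
    tau=st.floats(0.1, 10.0),
    mu=st.floats(0.1, 10.0),
    u=st.floats(0.05, 1.0),
    c=st.floats(0.05, 2.0),
    v_eq=st.floats(-0.5, 0.95),
)


class TestEventMap:
    def test_full_relaxation_limit(self, fig2a):
        big = 1e3 * max(fig2a.tau, fig2a.mu)
        out = event_map_step(NeuronState(0.3, 0.4), fig2a, big)
        assert out.x == pytest.approx(1.0)
        assert out.v == pytest.approx(fig2a.v_eq + fig2a.c)

    def test_no_depletion_keeps_full_resources(self, fig2a):
        p = TMLIFParams(tau=1.0, mu=10.0, u=1e-300, c=0.5, v_eq=0.8)
        # u -> 0 limit: x = 1 is invariant for any interval
        for interval in (0.1, 1.0, 17.0):
            assert event_map_step(NeuronState(0.0, 1.0), p, interval).x == \
                pytest.approx(1.0)

    def test_matches_ode_with_jumps_oracle(self, fig2a):
        xs = resource_fixed_point(fig2a, 1.0)
        state = NeuronState(0.0, xs)
        mapped = event_map_step(state, fig2a, 1.0)
        oracle = ode_event_map_oracle(state, fig2a, 1.0)
        assert mapped.v == pytest.approx(oracle.v, rel=1e-8)
        assert mapped.x == pytest.approx(oracle.x, rel=1e-8)

    def test_invalid_interval(self, fig2a):
        with pytest.raises(ValueError):
            event_map_step(NeuronState(0.0, 1.0), fig2a, 0.0)


class TestResourceFixedPoint:
    def test_long_period_limit(self, fig2a):
        assert resource_fixed_point(fig2a, 1e6) == pytest.approx(1.0)

    def test_full_depletion_formula(self):
        p = TMLIFParams(tau=1.0, mu=2.0, u=1.0, c=0.5, v_eq=0.0)
        T = 0.7
        assert resource_fixed_point(p, T) == pytest.approx(1 - math.exp(-T / 2.0))

    def test_equals_fixed_point_iteration(self, fig2a):
        # iterate only the resource row from x = 1 until convergence
        T, p = 1.0, fig2a
        x = 1.0
        for _ in range(10_000):
            x_new = x * (1 - p.u) * math.exp(-T / p.mu) + 1 - math.exp(-T / p.mu)
            if abs(x_new - x) < 1e-14:
                break
            x = x_new
        assert resource_fixed_point(p, T) == pytest.approx(x, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(params=valid_params, t1=st.floats(0.01, 50.0), scale=st.floats(1.01, 10.0))
    def test_monotone_in_period(self, params, t1, scale):
        """More recovery time leaves more resources available."""
        assert resource_fixed_point(params, t1 * scale) >= \
            resource_fixed_point(params, t1)

    def test_invalid_period(self, fig2a):
        with pytest.raises(ValueError):
            resource_fixed_point(fig2a, -1.0)


class TestPotentialStaircase:
    def test_first_step(self, fig2a):
        T = 0.8
        xs = resource_fixed_point(fig2a, T)
        expected = fig2a.c * xs + fig2a.v_eq * (1 - math.exp(-T / fig2a.tau))
        assert potential_after_n(fig2a, T, 1) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(params=valid_params, period=st.floats(0.05, 20.0), n=st.integers(1, 50))
    def test_geometric_sum_identity(self, params, period, n):
        """Closed form equals the explicit exponential sum term by term."""
        xs = resource_fixed_point(params, period)
        et = math.exp(-period / params.tau)
        explicit = params.c * xs * sum(et ** (n - m) for m in range(1, n + 1)) \
            + params.v_eq * (1 - et ** n)
        assert potential_after_n(params, period, n) == \
            pytest.approx(explicit, rel=1e-12, abs=1e-12)

    def test_large_n_limit(self, fig2a):
        T = 0.8
        xs = resource_fixed_point(fig2a, T)
        limit = fig2a.c * xs / (1 - math.exp(-T / fig2a.tau)) + fig2a.v_eq
        assert potential_after_n(fig2a, T, 10_000) == pytest.approx(limit)

    def test_invalid_n(self, fig2a):
        with pytest.raises(ValueError):
            potential_after_n(fig2a, 1.0, 0)


class TestSpikesToThreshold:
    def test_strong_slow_input_fires_first_spike(self):
        p = TMLIFParams(tau=1.0, mu=1.0, u=0.1, c=0.5, v_eq=0.6)
        # slow input: x* ~ 1 and c + v_eq = 1.1 > 1
        assert spikes_to_threshold(p, 100.0) == 1

    def test_fig5c_silent_at_low_rate(self, fig5c):
        assert spikes_to_threshold(fig5c, 1.0 / 0.1) is None

    def test_matches_direct_iteration(self, fig2a):
        for T in np.linspace(0.35, 5.0, 40):
            assert spikes_to_threshold(fig2a, float(T)) == \
                iterate_to_threshold(fig2a, float(T))

    def test_matches_direct_iteration_random_params(self):
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 200:
            p = TMLIFParams(
                tau=rng.uniform(0.2, 5.0), mu=rng.uniform(0.2, 5.0),
                u=rng.uniform(0.1, 1.0), c=rng.uniform(0.1, 1.5),
                v_eq=rng.uniform(-0.5, 0.9))
            rate = rng.uniform(0.05, 5.0)
            n_theory = spikes_to_threshold(p, 1.0 / rate)
            n_oracle = iterate_to_threshold(p, 1.0 / rate, cap=100_000)
            assert n_theory == n_oracle
            checked += 1


class TestClosedFormRate:
    def test_silent_regime_returns_zero(self, fig5c):
        assert closed_form_rate(fig5c, 0.1) == 0.0

    def test_plateau_level(self, fig2a):
        """Mean response over a uniform high-rate grid sits near 0.3."""
        grid = np.linspace(0.5, 3.0, 500)
        mean_out = np.mean([closed_form_rate(fig2a, r) for r in grid])
        assert mean_out == pytest.approx(0.3, rel=0.2)

    def test_linear_within_locking_band(self, fig2a):
        """Within one band (constant n_tilde) the response is exactly
        rate_in / n_tilde."""
        grid = np.linspace(0.2, 3.0, 300)
        for r in grid:
            res = theory_result(fig2a, float(r))
            assert res.rate_out == r / res.n_tilde

    def test_silent_iff_asymptote_below_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = TMLIFParams(
                tau=rng.uniform(0.2, 5.0), mu=rng.uniform(0.2, 5.0),
                u=rng.uniform(0.1, 1.0), c=rng.uniform(0.1, 1.5),
                v_eq=rng.uniform(-0.5, 0.9))
            rate = rng.uniform(0.05, 5.0)
            T = 1.0 / rate
            xs = resource_fixed_point(p, T)
            asymptote = p.c * xs / (1 - math.exp(-T / p.tau)) + p.v_eq
            assert (closed_form_rate(p, rate) == 0.0) == (asymptote < 1.0)

    def test_invalid_rate(self, fig2a):
        with pytest.raises(ValueError):
            closed_form_rate(fig2a, 0.0)


class TestCriticalFrequencies:
    def test_constant_band_has_no_jumps(self, fig2a):
        # inside the 1:1 band at low rates n_tilde stays 1
        assert critical_frequencies(fig2a, (0.05, 0.2), 100) == []

    def test_slow_recovery_only_downward(self, fig2a):
        jumps = critical_frequencies(fig2a, (0.05, 3.0), 2000)
        assert jumps and all(d == "downward" for _, d in jumps)

    def test_equal_timescales_both_directions(self, fig2b):
        dirs = {d for _, d in critical_frequencies(fig2b, (0.05, 6.0), 2000)}
        assert {"upward", "downward"} <= dirs

    def test_invalid_range(self, fig2a):
        with pytest.raises(ValueError):
            critical_frequencies(fig2a, (2.0, 1.0), 100)


def test_theory_curve_schema(fig2b):
    df = theory_curve(fig2b, np.linspace(0.1, 6.0, 50))
    assert list(df.columns) == ["rate_in", "rate_out", "n_tilde", "silent_flag"]
    assert df["silent_flag"].iloc[0]  # low-rate silence for this set
    assert (df.loc[~df.silent_flag, "rate_out"] > 0).all()
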
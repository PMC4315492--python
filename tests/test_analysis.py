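"""Rate estimation, error bounds, locking classification, non-monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikelock import (
    LockingLabel,
    RateEstimate,
    ResponseCurve,
    SpikeTrain,
    classify_locking,
    detect_nonmonotonic,
    estimate_rate,
    experimental_error,
    generate_gamma,
    generate_periodic,
    simulated_error_bound,
    theory_curve,
    FIG2A,
)
from spikelock.trains import GammaInputSpec


class TestEstimateRate:
    @pytest.mark.parametrize("period,n", [(0.1, 100), (3.7, 5), (12.0, 2)])
    def test_exact_on_periodic_trains(self, period, n):
        est = estimate_rate(generate_periodic(period, n))
        assert est.rate == pytest.approx(1.0 / period, rel=1e-14)

    def test_single_spike_is_silent(self):
        est = estimate_rate(SpikeTrain(np.array([1.0]), 2.0))
        assert est.silent and est.rate == 0.0 and est.span is None

    def test_empty_train_is_silent(self):
        est = estimate_rate(SpikeTrain(np.empty(0), 2.0))
        assert est.silent and est.rate == 0.0


class TestExperimentalError:
    def test_one_to_one_locking_has_no_error(self):
        assert experimental_error(3.0, 3.0) == 0.0

    @pytest.mark.parametrize("rin,rout,expected", [(100, 50, 1.0), (150, 50, 2.0)])
    def test_arithmetic(self, rin, rout, expected):
        assert experimental_error(rin, rout) == pytest.approx(expected)

    def test_output_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            experimental_error(1.0, 2.0)


class TestSimulatedErrorBound:
    def test_hundred_spikes_give_one_percent(self):
        # span worth 100 spikes (rate*span = 100): relative bound 1%
        assert simulated_error_bound(2.0, 50.0) == pytest.approx(0.01)

    def test_vanishes_with_span(self):
        assert simulated_error_bound(1.0, 1e12) == pytest.approx(0.0, abs=1e-11)

    def test_brute_force_phase_offsets(self):
        """Enumerated worst case over counting-window phases of a periodic
        train stays below the 1/(rate*span) bound."""
        f, window = 0.3, 1e4
        period = 1.0 / f
        full = generate_periodic(period, int(f * (window + 10 * period)) + 2)
        worst = 0.0
        for phase in np.linspace(0.0, period, 25, endpoint=False):
            inside = full.times[(full.times >= phase)
                                & (full.times <= phase + window)]
            est = (len(inside) - 1) / (inside[-1] - inside[0])
            worst = max(worst, abs(est - f))
        bound = simulated_error_bound(f, window)
        assert bound == pytest.approx(1.0 / (0.3 * 1e4))
        assert worst <= bound

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulated_error_bound(0.0, 10.0)


class TestClassifyLocking:
    def test_every_third_input_is_three_to_one(self):
        inp = generate_periodic(1.0, 90)
        out = SpikeTrain(inp.times[::3], inp.duration)
        assert str(classify_locking(inp, out)) == "3:1"

    def test_complex_pattern_eleven_to_three(self):
        # outputs after cumulative counts 4, 4, 3 of inputs: 11 inputs / 3 outputs
        inp = generate_periodic(1.0, 121)
        picks = np.cumsum([4, 4, 3] * 10) - 1
        out = SpikeTrain(inp.times[picks], inp.duration)
        label = classify_locking(inp, out)
        assert (label.n, label.m) == (11, 3)

    def test_self_is_one_to_one(self):
        train = generate_gamma(GammaInputSpec(3.0, 1.0, 40, seed=2))
        assert str(classify_locking(train, train)) == "1:1"

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 60))
    def test_self_locking_property(self, seed, n):
        train = generate_gamma(GammaInputSpec(2.0, 1.0, n, seed=seed))
        assert str(classify_locking(train, train)) == "1:1"

    def test_rescaling_invariance(self):
        inp = generate_periodic(1.0, 60)
        out = SpikeTrain(inp.times[::2], inp.duration)
        a = classify_locking(inp, out)
        b = classify_locking(inp.rescaled(37.5), out.rescaled(37.5))
        assert (a.kind, a.n, a.m) == (b.kind, b.n, b.m)

    def test_random_thinning_is_irregular(self):
        """A coin-flip-thinned train can match a rational rate ratio but must
        not classify as locked (the count pattern is aperiodic)."""
        rng = np.random.default_rng(123)
        inp = generate_periodic(1.0, 400)
        keep = rng.random(400) < 0.5
        keep[0] = keep[-1] = True
        out = SpikeTrain(inp.times[keep], inp.duration)
        label = classify_locking(inp, out, tolerance=10.0)  # rate test moot
        assert label.kind == "irregular"

    def test_empty_output_is_silent(self):
        inp = generate_periodic(1.0, 10)
        assert classify_locking(inp, SpikeTrain(np.empty(0), inp.duration)).kind \
            == "silent"

    def test_locked_label_requires_coprime(self):
        with pytest.raises(ValueError):
            LockingLabel("locked", 4, 2)


def _curve_from_rates(rates_out, rates_in=None, err=0.0):
    curve = ResponseCurve()
    rates_in = rates_in or list(range(1, len(rates_out) + 1))
    for r_in, r_out in zip(rates_in, rates_out):
        curve.append(r_in, RateEstimate(r_out, 100, 10.0, err),
                     LockingLabel("irregular"))
    return curve


class TestDetectNonmonotonic:
    def test_increasing_curve_has_none(self):
        assert detect_nonmonotonic(_curve_from_rates([1, 2, 3, 4])) == []

    def test_theory_curve_has_downward_jumps(self):
        df = theory_curve(FIG2A, np.linspace(0.1, 3.0, 400))
        regions = detect_nonmonotonic(df)
        assert len(regions) >= 1
        # each detected decrease of the closed-form curve is a jump between
        # adjacent grid points (infinitely fast in the continuum limit)
        for start, end in regions:
            assert end == start + 1

    def test_error_bars_mask_small_decreases(self):
        curve = _curve_from_rates([1.0, 0.95, 1.2], err=0.1)
        assert detect_nonmonotonic(curve) == []

    def test_reversal_mirrors_regions(self):
        """Decreasing steps of the reversed curve are exactly the mirrored
        increasing steps of the forward curve."""
        rates = [1.0, 2.0, 1.5, 1.2, 2.5]
        n_steps = len(rates) - 1
        rev = detect_nonmonotonic(_curve_from_rates(rates[::-1]))
        rev_steps = {i for s, e in rev for i in range(s, e)}
        fwd_inc_steps = {i for i in range(n_steps) if rates[i + 1] > rates[i]}
        assert rev_steps == {n_steps - 1 - i for i in fwd_inc_steps}


class TestResponseCurveIO:
    def test_csv_roundtrip(self, tmp_path):
        curve = _curve_from_rates([0.5, 0.7, 0.6], err=0.01)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = ResponseCurve.from_csv(path)
        pd.testing.assert_frame_equal(back.to_frame(), curve.to_frame())

    def test_rate_in_must_increase(self):
        curve = _curve_from_rates([0.5])
        with pytest.raises(ValueError):
            curve.append(0.5, RateEstimate(1.0, 10, 1.0, 0.0),
                         LockingLabel("irregular"))
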
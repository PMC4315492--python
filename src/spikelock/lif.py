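"""Exact event-driven simulation of the LIF + depressing-synapse system.

Between input spikes both state variables relax along their closed-form
interval solutions, so there is no ODE-stepping error: the simulator is an
exact implementation of the event map with threshold and reset applied.
At each input time the potential is kicked by ``c`` times the resource
level *before* depletion, the resources are depleted by the fraction ``u``,
and if the kicked potential reaches threshold (V >= 1) an output spike is
recorded at that input time and V is reset to 0.  Because the neuron is
excitable (v_eq < 1), output spike times are a subset of input spike times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .analysis import (
    LockingLabel,
    RateEstimate,
    ResponseCurve,
    classify_locking,
    estimate_rate,
    simulated_error_bound,
)
from .theory import NeuronState, TMLIFParams
from .trains import GammaInputSpec, SpikeTrain, generate_gamma, generate_periodic

__all__ = ["SimResult", "simulate_tm_lif", "stationary_rate", "response_curve_lif"]

# hard cap on input events when hunting for output spikes of a (possibly
# silent) neuron; generous relative to any n_tilde met in practice
_MAX_INPUT_EVENTS = 200_000


@dataclass(frozen=True)
class SimResult:
    """Output of one simulation run."""

    output_train: SpikeTrain
    final_state: NeuronState
    trajectory: Optional[np.ndarray] = None  # columns (t, V, x) if recorded

    @property
    def n_output(self) -> int:
        return len(self.output_train)


def simulate_tm_lif(
    params: TMLIFParams,
    input_train: SpikeTrain,
    initial_state: Optional[NeuronState] = None,
    record_trajectory: bool = False,
) -> SimResult:
    """Drive the LIF + depressing synapse with an arbitrary spike train.

    ``initial_state`` defaults to (v_eq, 1): resting potential, full
    resources.  The returned trajectory (if requested) samples (t, V, x)
    right after each input event.
    """
    times = input_train.times
    if times.size == 0:
        raise ValueError("input train must contain at least one event")
    state = initial_state if initial_state is not None else NeuronState(params.v_eq, 1.0)
    v, x = float(state.v), float(state.x)
    if not 0.0 <= x <= 1.0:
        raise ValueError("initial resource level must lie in [0, 1]")

    tau, mu, u, c, v_eq = params.tau, params.mu, params.u, params.c, params.v_eq
    out_times = []
    traj = [] if record_trajectory else None

    t_prev = 0.0
    exp = np.exp
    for t in times:
        dt = t - t_prev
        if dt > 0:
            # closed-form relaxation between events
            et = exp(-dt / tau) if dt / tau < 700.0 else 0.0
            em = exp(-dt / mu) if dt / mu < 700.0 else 0.0
            v = (v - v_eq) * et + v_eq
            x = 1.0 - (1.0 - x) * em
        # kick with pre-depletion resources, then deplete, then test
        v += c * x
        x *= 1.0 - u
        if v >= 1.0:
            out_times.append(t)
            v = 0.0
        if traj is not None:
            traj.append((t, v, x))
        t_prev = t

    out = SpikeTrain(np.asarray(out_times, dtype=float), input_train.duration,
                     input_train.unit)
    trajectory = np.asarray(traj) if traj is not None else None
    return SimResult(out, NeuronState(v, x), trajectory)


def stationary_rate(
    params: TMLIFParams,
    rate_in: float,
    min_duration: Optional[float] = None,
    min_spikes: int = 100,
    transient: Optional[float] = None,
    input_train: Optional[SpikeTrain] = None,
    silent_cap_events: int = 5000,
) -> Tuple[RateEstimate, SpikeTrain]:
    """Stationary output rate of the driven system, with its error bound.

    Discards an initial transient (default ``20 * max(tau, mu)``, long
    enough for the resource fixed point to be reached to high accuracy),
    then extends the run until at least ``min_spikes`` output spikes fall
    after the transient and ``min_duration`` is covered, or a hard cap on
    input events is hit (silent neurons).  The rate is the spike-count
    estimator (N - 1) / span; the reported error is 1 / (rate * span).

    A pre-generated ``input_train`` (e.g. gamma-jittered) may be supplied;
    otherwise a periodic train at ``rate_in`` is built internally.
    Returns the estimate and the post-transient output train.
    """
    if rate_in <= 0:
        raise ValueError("input rate must be positive")
    if transient is None:
        transient = 20.0 * max(params.tau, params.mu)
    if min_duration is None:
        min_duration = max(2.0 * transient, min_spikes / rate_in)
    if min_duration <= transient:
        raise ValueError("min_duration must exceed the transient")

    period = 1.0 / rate_in

    def run(duration: float) -> SpikeTrain:
        if input_train is not None:
            train = input_train
        else:
            n_ev = min(int(np.ceil(duration / period)) + 1, _MAX_INPUT_EVENTS)
            train = generate_periodic(period, n_ev)
        return simulate_tm_lif(params, train).output_train

    duration = min_duration
    while True:
        out = run(duration)
        post = out.times[out.times >= transient]
        n_inputs_used = duration / period
        if len(post) >= min_spikes or input_train is not None:
            break
        if len(post) == 0 and n_inputs_used >= silent_cap_events:
            break  # no output after thousands of inputs: silent
        if n_inputs_used >= _MAX_INPUT_EVENTS:
            break
        # not enough output spikes yet: extend, scaling by the deficit
        if len(post) == 0:
            duration = transient + period * silent_cap_events
        else:
            grow = max(2.0, min_spikes / len(post))
            duration = min(duration * grow, period * _MAX_INPUT_EVENTS)

    post_train = SpikeTrain(post - transient if len(post) else np.empty(0),
                            max(out.duration - transient, 0.0), out.unit)
    est = estimate_rate(post_train)
    if est.rate > 0 and est.span and est.span > 0:
        # absolute (rate-scale) error bar: rate * relative bound = 1/span
        abs_err = est.rate * simulated_error_bound(est.rate, est.span)
        est = RateEstimate(est.rate, est.n_spikes, est.span, abs_err)
    return est, post_train


def response_curve_lif(
    params: TMLIFParams,
    rate_grid,
    alpha: float | None = None,
    n_events: int = 4000,
    seed: int = 0,
    min_spikes: int = 100,
    transient: float | None = None,
    max_n: int = 25,
    max_m: int = 10,
) -> ResponseCurve:
    """Simulated response curve of the LIF + depressing synapse.

    With ``alpha=None`` the input at each grid rate is strictly periodic and
    the run length adapts until ``min_spikes`` output spikes are counted.
    With a finite ``alpha`` the input intervals are gamma-jittered with that
    shape parameter (relative interval std ``1/sqrt(alpha)``); each grid
    point uses an independent, reproducible substream derived from ``seed``.
    """
    if transient is None:
        transient = 20.0 * max(params.tau, params.mu)
    curve = ResponseCurve(params={
        "model": "lif_tm", "tau": params.tau, "mu": params.mu, "u": params.u,
        "c": params.c, "v_eq": params.v_eq, "alpha": alpha, "seed": seed,
    })
    for i, rate in enumerate(rate_grid):
        rate = float(rate)
        if alpha is None:
            est, out_post = stationary_rate(
                params, rate, min_spikes=min_spikes, transient=transient)
            period = 1.0 / rate
            n_in = int(np.ceil((out_post.duration + transient) / period)) + 1
            in_train = generate_periodic(period, n_in)
        else:
            spec = GammaInputSpec(alpha, rate, n_events, seed=seed + i)
            in_train = generate_gamma(spec)
            est, out_post = stationary_rate(
                params, rate, min_spikes=min_spikes, transient=transient,
                input_train=in_train)
        if est.silent:
            label = LockingLabel("silent")
        else:
            in_post = in_train.crop(transient)
            label = classify_locking(in_post, out_post, max_n=max_n, max_m=max_m)
        curve.append(rate, est, label)
    return curve
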
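"""FitzHugh-Nagumo and Hodgkin-Huxley neurons driven by spike trains.

Both models receive input through a static synapse: every input spike adds
one copy of a causal synaptic kernel to the drive.  The kernels used are

* FHN: a difference of exponentials ``K(t) = 2 (exp(-t) - exp(-2 t))``,
* HH: a normalized alpha function ``K(t) = e * (t / tau_ex) *
  exp(-t / tau_ex)`` whose peak value is 1 at ``t = tau_ex``.

Rather than summing over the spike history at every step, each kernel is
represented exactly by auxiliary linear ODE states that are incremented at
spike arrival times (a biexponential needs two decaying states, the alpha
function a decaying state feeding a second one).  The full system is then
integrated piecewise between input spikes with an adaptive Runge-Kutta
scheme; output spikes are upward crossings of a detection threshold, found
by the integrator's event location and pruned by a refractory time.

Units: the FHN model is dimensionless as printed; HH uses mV / ms /
uA/cm^2 / mS/cm^2 / uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .analysis import (
    LockingLabel,
    RateEstimate,
    ResponseCurve,
    classify_locking,
    estimate_rate,
    simulated_error_bound,
)
from .lif import SimResult
from .trains import SpikeTrain, generate_periodic

__all__ = [
    "FHNParams",
    "HHParams",
    "SpikeDetectionSpec",
    "FHN_FIG3",
    "HH_FIG4",
    "FHN_DETECTION",
    "HH_DETECTION",
    "synaptic_drive",
    "simulate_fhn",
    "simulate_hh",
    "response_curve_ode",
]


@dataclass(frozen=True)
class BiexpKernel:
    """Difference-of-exponentials kernel amp*(exp(-k_slow t) - exp(-k_fast t)).

    Causal (zero for t < 0) and zero at t = 0 since k_fast > k_slow.
    """

    amp: float = 2.0
    k_slow: float = 1.0
    k_fast: float = 2.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.amp * (np.exp(-self.k_slow * np.clip(t, 0, None))
                          - np.exp(-self.k_fast * np.clip(t, 0, None)))
        return np.where(t >= 0, out, 0.0)

    @property
    def support(self) -> float:
        """Effective support: 12 slow time constants."""
        return 12.0 / self.k_slow


@dataclass(frozen=True)
class AlphaKernel:
    """Normalized alpha function e * (t/tau) * exp(-t/tau); peak 1 at t=tau."""

    tau: float = 1.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.clip(t, 0, None) / self.tau
        return np.where(t >= 0, math.e * tt * np.exp(-tt), 0.0)

    @property
    def support(self) -> float:
        return 12.0 * self.tau


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh-Nagumo neuron with a cubic fast nullcline.

    a sets the equilibrium membrane potential, b the channel opening rate,
    c the input strength, mu_prime the gating (recovery) time constant.
    """

    a: float = 0.139
    b: float = 2.54
    c: float = 0.5
    mu_prime: float = 125.0
    kernel: BiexpKernel = field(default_factory=BiexpKernel)

    def __post_init__(self) -> None:
        if self.mu_prime <= 0:
            raise ValueError("gating time constant must be positive")

    def rest_state(self) -> Tuple[float, float]:
        """Rest fixed point of the unforced system (V = 0, W = 0 for the
        printed cubic: -V(V-1)(V-a) = W together with V = b W)."""
        return 0.0, 0.0


@dataclass(frozen=True)
class HHParams:
    """Hodgkin-Huxley neuron (standard squid-axon rate functions).

    Conductances in mS/cm^2, potentials in mV, currents in uA/cm^2,
    capacitance in uF/cm^2, time in ms.  i0 is a constant bias current;
    eps the peak amplitude of a single synaptic input.
    """

    C: float = 2.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    v_na: float = 50.0
    v_k: float = -77.0
    v_l: float = -54.4
    i0: float = 5.0
    eps: float = 9.0
    tau_ex: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.g_na, self.g_k, self.g_l) < 0:
            raise ValueError("conductances must be non-negative")
        if self.tau_ex <= 0:
            raise ValueError("synaptic time constant must be positive")

    @property
    def kernel(self) -> AlphaKernel:
        return AlphaKernel(self.tau_ex)

    def rest_state(self, v0: float = -65.0) -> np.ndarray:
        """(V, m, n, h) with gates at steady state for potential v0."""
        am, bm, an, bn, ah, bh = _hh_rates(v0)
        return np.array([v0, am / (am + bm), an / (an + bn), ah / (ah + bh)])


@dataclass(frozen=True)
class SpikeDetectionSpec:
    """Upward threshold crossing with a refractory separation."""

    threshold: float
    refractory: float = 0.0

    def __post_init__(self) -> None:
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")


FHN_FIG3 = FHNParams()
HH_FIG4 = HHParams()
# FHN spikes approach V ~ 1; 0.5 sits midway between a and 1 so subthreshold
# humps of smaller amplitude are not counted.  HH spikes overshoot 0 mV.
FHN_DETECTION = SpikeDetectionSpec(threshold=0.5, refractory=5.0)
HH_DETECTION = SpikeDetectionSpec(threshold=0.0, refractory=1.0)


def synaptic_drive(
    train: SpikeTrain, kernel: Callable[[np.ndarray], np.ndarray],
    amplitude: float, t
) -> np.ndarray:
    """Kernel-summed drive amplitude * sum_m K(t - t_m) over past spikes.

    Reference implementation by direct summation (kernel truncated beyond
    its effective support); the simulators use the equivalent auxiliary-ODE
    representation.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    if len(train):
        support = getattr(kernel, "support", np.inf)
        for tm in train.times:
            lag = t - tm
            mask = (lag >= 0) & (lag <= support)
            if np.any(mask):
                out[mask] += kernel(lag[mask])
    result = amplitude * out
    return result if result.size > 1 else float(result[0])


def _hh_rates(v: float) -> Tuple[float, float, float, float, float, float]:
    """Voltage-dependent gate rate functions (alpha_m, beta_m, alpha_n,
    beta_n, alpha_h, beta_h), with the removable singularities at
    v = -40 and v = -55 filled by their limits."""
    dv40 = v + 40.0
    if abs(dv40) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * dv40 / (1.0 - math.exp(-dv40 / 10.0))
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    dv55 = v + 55.0
    if abs(dv55) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * dv55 / (1.0 - math.exp(-dv55 / 10.0))
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    return am, bm, an, bn, ah, bh


def _fhn_rhs(t, y, p: FHNParams):
    v, w, y1, y2 = y
    drive = p.kernel.amp * (y1 - y2)
    dv = -v * (v - 1.0) * (v - p.a) - w + p.c * drive
    dw = (v - p.b * w) / p.mu_prime
    return (dv, dw, -p.kernel.k_slow * y1, -p.kernel.k_fast * y2)


def _hh_rhs(t, y, p: HHParams):
    v, m, n, h, s1, s2 = y
    am, bm, an, bn, ah, bh = _hh_rates(v)
    i_ex = p.eps * math.e * s2
    i_ion = (
        p.g_na * m ** 3 * h * (v - p.v_na)
        + p.g_k * n ** 4 * (v - p.v_k)
        + p.g_l * (v - p.v_l)
    )
    dv = (i_ex + p.i0 - i_ion) / p.C
    return (
        dv,
        am * (1.0 - m) - bm * m,
        an * (1.0 - n) - bn * n,
        ah * (1.0 - h) - bh * h,
        -s1 / p.tau_ex,
        (s1 - s2) / p.tau_ex,
    )


def _integrate_driven(
    rhs,
    params,
    y0: np.ndarray,
    spike_jumps: Sequence[int],
    train: SpikeTrain,
    detection: SpikeDetectionSpec,
    t_end: float,
    rtol: float,
    atol: float,
    record: bool,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Piecewise integration with aux-state jumps (+1) at input spike times.

    Returns (crossing_times, final_state, trajectory).  ``spike_jumps``
    lists the state indices incremented by 1 at each input spike.
    """

    def event(t, y, *args):
        return y[0] - detection.threshold

    event.direction = 1.0

    breakpoints = [t for t in train.times if t <= t_end]
    edges = [0.0] + breakpoints + [t_end]
    y = np.array(y0, dtype=float)
    crossings: List[float] = []
    traj_t: List[np.ndarray] = []
    traj_y: List[np.ndarray] = []

    for k in range(len(edges) - 1):
        t0, t1 = edges[k], edges[k + 1]
        if k > 0:  # segment starts at an input spike: apply the kick
            for idx in spike_jumps:
                y[idx] += 1.0
        if t1 <= t0:
            continue
        sol = solve_ivp(
            rhs, (t0, t1), y, args=(params,), method="RK45",
            rtol=rtol, atol=atol, events=event, dense_output=False,
            t_eval=None,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t = {sol.t[-1]:g}: {sol.message}")
        crossings.extend(sol.t_events[0].tolist())
        y = sol.y[:, -1]
        if record:
            traj_t.append(sol.t)
            traj_y.append(sol.y)

    # refractory pruning
    kept: List[float] = []
    for tc in crossings:
        if not kept or tc - kept[-1] >= detection.refractory:
            kept.append(tc)
    trajectory = None
    if record:
        tt = np.concatenate(traj_t)
        yy = np.concatenate(traj_y, axis=1)
        trajectory = np.vstack([tt, yy]).T
    return np.asarray(kept), y, trajectory


def simulate_fhn(
    params: FHNParams,
    train: SpikeTrain,
    detection: SpikeDetectionSpec = FHN_DETECTION,
    duration: Optional[float] = None,
    initial_state: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    record_trajectory: bool = False,
) -> SimResult:
    """Integrate the forced FitzHugh-Nagumo system and detect output spikes.

    ``train`` may be empty (unforced relaxation to rest).  State vector is
    (V, W, y1, y2) with y1, y2 the kernel states.
    """
    if duration is None:
        duration = train.duration if len(train) else 100.0
    if initial_state is None:
        v0, w0 = params.rest_state()
        y0 = np.array([v0, w0, 0.0, 0.0])
    else:
        y0 = np.asarray(initial_state, dtype=float)
    spikes, y_end, traj = _integrate_driven(
        _fhn_rhs, params, y0, (2, 3), train, detection, duration,
        rtol, atol, record_trajectory,
    )
    out = SpikeTrain(spikes, duration, train.unit if len(train) else "dimensionless")
    from .theory import NeuronState  # (V, W) reported as the 2-d state

    return SimResult(out, NeuronState(float(y_end[0]), float(y_end[1])), traj)


def simulate_hh(
    params: HHParams,
    train: SpikeTrain,
    detection: SpikeDetectionSpec = HH_DETECTION,
    duration: Optional[float] = None,
    initial_state: Optional[Sequence[float]] = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    record_trajectory: bool = False,
) -> SimResult:
    """Integrate the forced Hodgkin-Huxley system and detect output spikes.

    State vector is (V, m, n, h, s1, s2) with s1, s2 the alpha-kernel
    states.  Gating variables stay in [0, 1] along trajectories.
    """
    if duration is None:
        duration = train.duration if len(train) else 100.0
    if initial_state is None:
        y0 = np.concatenate([params.rest_state(), [0.0, 0.0]])
    else:
        y0 = np.asarray(initial_state, dtype=float)
    spikes, y_end, traj = _integrate_driven(
        _hh_rhs, params, y0, (4,), train, detection, duration,
        rtol, atol, record_trajectory,
    )
    out = SpikeTrain(spikes, duration, train.unit if len(train) else "ms")
    from .theory import NeuronState

    return SimResult(out, NeuronState(float(y_end[0]), float(y_end[1])), traj)


def response_curve_ode(
    model: str,
    params,
    rate_grid: Sequence[float],
    duration: float,
    detection: Optional[SpikeDetectionSpec] = None,
    transient: Optional[float] = None,
    max_n: int = 20,
    max_m: int = 10,
    **sim_kwargs,
) -> ResponseCurve:
    """Stationary response curve of an ODE neuron over a grid of input rates.

    For each rate a periodic train covering ``duration`` is simulated, the
    first ``transient`` (default: 10% of the run, at least 200 time units)
    is discarded, and the remaining output is rate-estimated and locking-
    classified against the input.
    """
    if model not in ("fhn", "hh"):
        raise ValueError("model must be 'fhn' or 'hh'")
    simulate = simulate_fhn if model == "fhn" else simulate_hh
    if detection is None:
        detection = FHN_DETECTION if model == "fhn" else HH_DETECTION
    if transient is None:
        transient = max(0.1 * duration, 200.0)
    if transient >= duration:
        raise ValueError("duration must exceed the transient")
    unit = "dimensionless" if model == "fhn" else "ms"
    curve = ResponseCurve(params={"model": model, "params": str(params),
                                  "duration": duration, "transient": transient})
    for rate in rate_grid:
        rate = float(rate)
        period = 1.0 / rate
        n_ev = int(np.ceil(duration / period)) + 1
        train = generate_periodic(period, n_ev, unit=unit)
        try:
            result = simulate(params, train, detection, duration=duration,
                              **sim_kwargs)
        except RuntimeError as exc:
            raise RuntimeError(f"integration failed at rate_in = {rate:g}") from exc
        out_post = result.output_train.crop(transient)
        in_post = train.crop(transient)
        est = estimate_rate(out_post)
        if not est.silent:
            abs_err = est.rate * simulated_error_bound(est.rate, est.span)
            est = RateEstimate(est.rate, est.n_spikes, est.span, abs_err)
            label = classify_locking(in_post, out_post, max_n=max_n, max_m=max_m)
        else:
            label = LockingLabel("silent")
        curve.append(rate, est, label)
    return curve
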
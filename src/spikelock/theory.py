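"""Closed-form stationary response of a LIF neuron with a depressing synapse.

Model
-----
A leaky integrate-and-fire neuron with membrane time constant ``tau``,
equilibrium potential ``v_eq`` (threshold fixed at 1, reset at 0) receives
delta inputs through a Tsodyks-Markram depressing synapse: each arriving
spike depletes a fraction ``u`` of the available resources ``x`` and kicks
the potential by ``c * x`` with the resource level at arrival; between
spikes ``x`` recovers toward 1 with time constant ``mu`` and ``V`` relaxes
toward ``v_eq`` with time constant ``tau``.  With ``v_eq < 1`` the neuron is
excitable: it can only fire at input times.

For strictly periodic input with period ``T`` the dynamics collapse onto a
discrete event map from one input time to the next.  The resource component
has a globally stable fixed point

    x*(T) = (1 - exp(-T/mu)) / (1 - (1-u) exp(-T/mu))

and, starting from reset with resources at the fixed point, the potential
right after the n-th input is

    V_n = (1 - exp(-n T/tau)) * (c x* / (1 - exp(-T/tau)) + v_eq).

The number of input spikes needed to reach threshold, ``n_tilde``, follows
in closed form, and the stationary output rate is ``rate_in / n_tilde`` (or
0 if the asymptote of ``V_n`` stays below 1).  Because ``n_tilde`` is an
integer the response curve is piecewise linear with slope ``1/n_tilde`` and
jumps at critical input rates -- downward whenever ``n_tilde`` increases
with the input rate, which is what makes the response non-monotonic.

Ceiling convention: the count uses the *strictly larger* integer, i.e. an
exact integer argument z maps to z + 1.  This matters only on the
measure-zero set where the threshold is reached exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "TMLIFParams",
    "NeuronState",
    "TheoryResult",
    "event_map_step",
    "resource_fixed_point",
    "potential_after_n",
    "spikes_to_threshold",
    "closed_form_rate",
    "theory_result",
    "critical_frequencies",
    "theory_curve",
    "FIG2A",
    "FIG2B",
    "FIG5C",
]

# ratio beyond which exp(-ratio) is treated as exactly 0 (asymptotic limit)
_EXP_UNDERFLOW = 700.0


def _edecay(ratio: float) -> float:
    """exp(-ratio) with an explicit asymptotic guard for huge ratios."""
    if ratio > _EXP_UNDERFLOW:
        return 0.0
    return math.exp(-ratio)


@dataclass(frozen=True)
class TMLIFParams:
    """Parameters of the LIF + depressing-synapse system.

    tau: membrane time constant; mu: resource recovery time constant;
    u: fraction of resources depleted per spike, in (0, 1]; c: maximum
    single-spike potential kick; v_eq: equilibrium potential (< 1 for an
    excitable neuron).  Threshold and reset are fixed at 1 and 0.
    """

    tau: float
    mu: float
    u: float
    c: float
    v_eq: float
    v_theta: float = 1.0
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.mu <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.u <= 1:
            raise ValueError("depletion fraction u must be in (0, 1]")
        if self.v_eq >= self.v_theta:
            raise ValueError("v_eq must be below threshold (excitable regime)")
        if self.v_theta != 1.0 or self.v_reset != 0.0:
            raise ValueError("threshold/reset are fixed at 1 and 0")

    def replace(self, **kw) -> "TMLIFParams":
        return replace(self, **kw)


class NeuronState(NamedTuple):
    """(V, x) state; at input times V is post-reception, x pre-transmission."""

    v: float
    x: float


class TheoryResult(NamedTuple):
    """Stationary response at one input rate."""

    n_tilde: Optional[int]  # None when silent
    x_star: float
    rate_out: float

    @property
    def silent(self) -> bool:
        return self.n_tilde is None


# Parameter sets of the two reference response curves and the
# silent-at-low-rate example used throughout the package.
FIG2A = TMLIFParams(tau=1.0, mu=10.0, u=0.2, c=0.5, v_eq=0.8)
FIG2B = TMLIFParams(tau=1.0, mu=1.0, u=0.4, c=0.8, v_eq=0.0)
FIG5C = TMLIFParams(tau=4.0, mu=1.0, u=0.2, c=0.5, v_eq=0.0)


def event_map_step(
    state: NeuronState, params: TMLIFParams, interval: float
) -> NeuronState:
    """Advance (V, x) across one inter-spike interval of length ``interval``.

    Implements the exact event map: the resource row depletes at the
    departing spike and recovers over the interval; the potential row decays
    toward ``v_eq`` and is kicked by ``c`` times the resource level at the
    arriving spike (the updated x).  No threshold/reset is applied here.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if not 0 <= state.x <= 1:
        raise ValueError("resource level x must lie in [0, 1]")
    em = _edecay(interval / params.mu)
    et = _edecay(interval / params.tau)
    x_new = state.x * (1.0 - params.u) * em + (1.0 - em)
    v_new = (state.v - params.v_eq) * et + params.v_eq + params.c * x_new
    return NeuronState(v_new, x_new)


def resource_fixed_point(params: TMLIFParams, period: float) -> float:
    """Globally stable fixed point x*(T) of the resource dynamics."""
    if period <= 0:
        raise ValueError("period must be positive")
    em = _edecay(period / params.mu)
    return (1.0 - em) / (1.0 - (1.0 - params.u) * em)


def potential_after_n(params: TMLIFParams, period: float, n: int) -> float:
    """Membrane potential right after the n-th input, starting from reset
    with resources at the fixed point x*(T)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if period <= 0:
        raise ValueError("period must be positive")
    xs = resource_fixed_point(params, period)
    et = _edecay(period / params.tau)
    ent = _edecay(n * period / params.tau)
    return (1.0 - ent) * (params.c * xs / (1.0 - et) + params.v_eq)


def _strict_ceil(z: float) -> int:
    """Smallest integer strictly larger than z (integer z maps to z + 1)."""
    return math.floor(z) + 1


def spikes_to_threshold(params: TMLIFParams, period: float) -> Optional[int]:
    """Number of input spikes needed to reach threshold, or None if silent.

    Silent means the asymptote of the stationary potential staircase,
    ``c x*/(1 - exp(-T/tau)) + v_eq``, never reaches 1.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    xs = resource_fixed_point(params, period)
    et = _edecay(period / params.tau)
    asymptote = params.c * xs / (1.0 - et) + params.v_eq
    if asymptote < 1.0 or math.isclose(asymptote, 1.0, rel_tol=0.0, abs_tol=1e-15):
        return None
    z = -(params.tau / period) * math.log(1.0 - 1.0 / asymptote)
    return max(1, _strict_ceil(z))


def closed_form_rate(params: TMLIFParams, rate_in: float) -> float:
    """Stationary output rate ``rate_in / n_tilde`` (0 when silent)."""
    if rate_in <= 0:
        raise ValueError("input rate must be positive")
    n = spikes_to_threshold(params, 1.0 / rate_in)
    return 0.0 if n is None else rate_in / n


def theory_result(params: TMLIFParams, rate_in: float) -> TheoryResult:
    """Full stationary description (n_tilde, x*, rate_out) at one rate."""
    if rate_in <= 0:
        raise ValueError("input rate must be positive")
    period = 1.0 / rate_in
    xs = resource_fixed_point(params, period)
    n = spikes_to_threshold(params, period)
    rate_out = 0.0 if n is None else rate_in / n
    return TheoryResult(n, xs, rate_out)


def critical_frequencies(
    params: TMLIFParams,
    rate_range: Tuple[float, float],
    resolution: int = 2000,
) -> List[Tuple[float, str]]:
    """Input rates where the locking integer n_tilde changes.

    Scans a uniform grid over ``rate_range`` and reports the midpoint of
    every adjacent pair across which n_tilde changes, tagged "upward"
    (n_tilde decreases, so the output rate jumps up) or "downward"
    (n_tilde increases -- the response drops although the input speeds up).
    Silent points are treated as n_tilde = +inf, so a silent-to-spiking
    onset registers as an upward jump.
    """
    lo, hi = rate_range
    if not (0 < lo < hi):
        raise ValueError("rate range must satisfy 0 < lo < hi")
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    grid = np.linspace(lo, hi, resolution)
    n_vals = [
        spikes_to_threshold(params, 1.0 / r) for r in grid
    ]
    n_eff = [math.inf if n is None else n for n in n_vals]
    jumps: List[Tuple[float, str]] = []
    for i in range(len(grid) - 1):
        if n_eff[i + 1] != n_eff[i]:
            direction = "upward" if n_eff[i + 1] < n_eff[i] else "downward"
            jumps.append((float(0.5 * (grid[i] + grid[i + 1])), direction))
    return jumps


def theory_curve(
    params: TMLIFParams, rates: Sequence[float]
) -> pd.DataFrame:
    """Closed-form response curve over a grid of input rates.

    Columns: rate_in, rate_out, n_tilde (NaN when silent), silent_flag.
    """
    rows = []
    for r in rates:
        res = theory_result(params, float(r))
        rows.append(
            {
                "rate_in": float(r),
                "rate_out": res.rate_out,
                "n_tilde": np.nan if res.silent else res.n_tilde,
                "silent_flag": res.silent,
            }
        )
    return pd.DataFrame(rows)
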
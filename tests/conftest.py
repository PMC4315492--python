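"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they check: the LIF system is
re-integrated with a fine-step RK4 scheme plus explicit jump conditions, and
the threshold count is re-derived by direct iteration of the event map.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikelock import FIG2A, FIG2B, FIG5C, NeuronState, TMLIFParams


@pytest.fixture(scope="session")
def fig2a() -> TMLIFParams:
    return FIG2A


@pytest.fixture(scope="session")
def fig2b() -> TMLIFParams:
    return FIG2B


@pytest.fixture(scope="session")
def fig5c() -> TMLIFParams:
    return FIG5C


def rk4_relax(v: float, x: float, params: TMLIFParams, duration: float,
              n_steps: int = 20_000) -> tuple[float, float]:
    """Fine-step RK4 integration of the subthreshold relaxation ODEs
    dV/dt = (v_eq - V)/tau, dx/dt = (1 - x)/mu (no inputs)."""
    h = duration / n_steps
    y = np.array([v, x], dtype=float)

    def f(y):
        return np.array([(params.v_eq - y[0]) / params.tau,
                         (1.0 - y[1]) / params.mu])

    for _ in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return float(y[0]), float(y[1])


def ode_event_map_oracle(state: NeuronState, params: TMLIFParams,
                         interval: float) -> NeuronState:
    """One event-map step computed by brute force: apply the jump conditions
    of the delta input at the departing spike, RK4-relax across the
    interval, then apply the potential kick of the arriving spike.

    State convention matches the map: V post-reception, x pre-transmission.
    """
    v0 = state.v
    x0_post = state.x * (1.0 - params.u)  # depletion at the departing spike
    v1, x1 = rk4_relax(v0, x0_post, params, interval)
    return NeuronState(v1 + params.c * x1, x1)


def iterate_to_threshold(params: TMLIFParams, period: float,
                         cap: int = 200_000) -> int | None:
    """Direct-iteration oracle for the spike count: from (V, x) = (0, x*)
    apply the event map until V >= 1; None if the cap is reached."""
    from spikelock import event_map_step, resource_fixed_point

    xs = resource_fixed_point(params, period)
    state = NeuronState(0.0, xs)
    for n in range(1, cap + 1):
        state = event_map_step(state, params, period)
        if state.v >= 1.0:
            return n
    return None
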
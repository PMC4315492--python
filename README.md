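# spikelock

Non-monotonic response curves of spiking neurons driven by regular spike
sequences: closed-form theory, exact and ODE-based simulators, synthetic
input generators, and locking/rate analysis.

## The problem

Classical neuronal input–output characterisation uses continuous input
currents (*f–I* curves), which are monotonic: more input, more output. But
many neurons — auditory brainstem relays, central pattern generators,
pacemaker circuits — receive *regular spike sequences*, not smooth currents.
For such pulsed inputs the stationary output rate λ_out as a function of the
input rate λ_in is generically **non-monotonic**: increasing the input
frequency can *decrease* the output frequency. Three ingredients suffice:
discrete communication by pulses, locking of output to input spikes, and any
form of resource limitation in spike transmission.

This package is written for computational neuroscientists who want to
compute, simulate and detect this phenomenon quantitatively.

## The core model

A leaky integrate-and-fire (LIF) neuron with a short-term-depressing
(Tsodyks–Markram) synapse:

    dV/dt = (V_eq − V)/τ + c·x·Σ_m δ(t − t_m)
    dx/dt = (1 − x)/μ  − u·x·Σ_m δ(t − t_m)

with threshold V_Θ = 1 (reset to 0). Each input spike at t_m depletes a
fraction *u* of the synaptic resources *x* and kicks the potential by *c·x*.
For periodic input with period *T* the dynamics reduce to an exact event
map whose resource component has the globally stable fixed point

    x*(T) = (1 − e^(−T/μ)) / (1 − (1−u)·e^(−T/μ)).

Starting from reset, the potential right after the *n*-th input is
V_n = (1 − e^(−nT/τ))·(c·x*/(1 − e^(−T/τ)) + V_eq), so the number of inputs
needed per output spike, ñ, follows in closed form and

    λ_out = λ_in / ñ(λ_in).

Because ñ is an integer, the response curve is piecewise linear with slope
1/ñ and jumps at critical input rates; wherever ñ *increases* with λ_in the
curve jumps **down**. The same locking mechanism (without any dynamic
synapse) produces non-monotonic curves in FitzHugh–Nagumo and Hodgkin–Huxley
neurons, both included here with kernel-convolved synaptic drive.

## Worked example

```python
from spikelock import FIG2A, theory_result, stationary_rate, critical_frequencies

# closed-form stationary response at input rate 1.5 (slow-recovery set:
# tau=1, mu=10, u=0.2, c=0.5, V_eq=0.8)
res = theory_result(FIG2A, rate_in=1.5)
print(res.n_tilde, round(res.x_star, 4), res.rate_out)
# 5 0.2563 0.3
#   -> at rate 1.5 the depressed synapse leaves x* = 0.256 of its resources,
#      the neuron needs 5 inputs per output spike, so lambda_out = 1.5/5 = 0.3

# exact event-driven simulation agrees to machine precision
est, _ = stationary_rate(FIG2A, rate_in=1.5)
print(round(est.rate, 6), est.n_spikes)
# 0.3 180

# critical input rates where the locking integer changes
print(critical_frequencies(FIG2A, (0.05, 3.0), 2000)[:2])
# [(0.4374, 'downward'), (0.7738, 'downward')]
#   -> both jumps lower the output while the input speeds up: non-monotonic
```

The numbered scripts under `analysis/` reproduce the full study: input
generators (`01`), closed-form curves and jump structure (`02`), the
theory-vs-simulation equivalence and slow frequency sweeps (`03`),
FitzHugh–Nagumo and Hodgkin–Huxley response curves with locking labels
(`04`), and robustness to gamma-jittered input timing (`05`). Each writes
CSV/JSON under `results/`. The same reproductions are available as
`spikelock figure fig2a`, `... fig5c` from the shell; `spikelock --help`
lists the generator, simulator and analysis subcommands.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the Hodgkin–Huxley locking ratio under a 170 Hz
periodic drive (measured after a 200 ms transient and confirmed by the
locking classifier); the saturation level of the closed-form LIF response
curve as the mean output rate over a 500-point grid of input rates in
[0.5, 3]; and the worst-case relative error of the spike-count rate
estimator (N−1)/span on periodic trains with ≥ 100 spikes per counting
window, maximised over frequencies and window phases.

## Layout

- `src/spikelock/trains.py` — spike-train container, periodic / gamma /
  sweep generators, text & JSON I/O
- `src/spikelock/theory.py` — event map, resource fixed point, closed-form
  response curve, critical frequencies
- `src/spikelock/lif.py` — exact event-driven LIF + depressing-synapse
  simulator, stationary-rate measurement
- `src/spikelock/neurons.py` — FitzHugh–Nagumo and Hodgkin–Huxley models
  with synaptic kernels and spike detection
- `src/spikelock/analysis.py` — rate estimators, error bounds, n:m locking
  classification, non-monotonicity detection
- `src/spikelock/figures.py`, `cli.py` — figure pipeline and `spikelock` CLI

See `docs/methods.md` for the modelling assumptions, numerical choices and
limitations.
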
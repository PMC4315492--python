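# Methods

This note documents the models, conventions and numerical choices behind
`spikelock`, and what the synthetic-data generators do and do not emulate.

## Models

### LIF neuron with a depressing synapse

State `(V, x)`: membrane potential and available synaptic resources.
Between input spikes both variables relax exponentially (`V → V_eq` with
time constant `τ`, `x → 1` with time constant `μ`). At an input spike the
potential is kicked by `c·x` with the resource level *before* depletion,
then `x` is depleted by the fraction `u`. If the kicked potential reaches
the threshold `V_Θ = 1` the neuron emits an output spike at that input time
and resets to `V = 0`. With `V_eq < 1` the neuron is excitable: output
spikes can only occur at input times, which is what makes locking
structural rather than emergent.

State convention at input times (used consistently by the event map, the
theory and the simulator): `V(t_m)` is the potential directly *after*
reception of the spike, `x(t_m)` the resource level directly *before*
transmission. The simulator implements the interval solutions in closed
form, so it is exact — the only "integration error" anywhere in the LIF
path is floating-point roundoff, and the theory–simulation equivalence
test demands agreement at every grid point within the rate-estimator
bound (in practice ~1e-16).

Parameters (dimensionless time): `tau` (membrane), `mu` (recovery),
`u ∈ (0, 1]` (depletion fraction), `c` (maximal kick), `v_eq < 1`.
Reference sets: slow recovery `(1, 10, 0.2, 0.5, 0.8)`, equal timescales
`(1, 1, 0.4, 0.8, 0)`, silent-onset `(4, 1, 0.2, 0.5, 0)`.

### Closed-form response

`spikes_to_threshold` uses the *strictly-larger-integer* ceiling: an exact
integer argument maps to the next integer. This convention differs from the
standard ceiling only on the measure-zero set where the stationary potential
staircase hits the threshold exactly; the simulator's reset rule (fire at
`V ≥ 1`) matches the standard ceiling on that degenerate set. Tests avoid
the degenerate set; for random parameters the two conventions agree with
probability one. Silence is declared when the staircase asymptote
`c·x*/(1 − e^(−T/τ)) + V_eq` is below 1 (evaluated with an absolute guard of
1e-15 at equality, where the required count diverges).

For `T/τ` or `T/μ` beyond 700 the exponentials are replaced by their
asymptotic limit 0 to avoid underflow warnings; this is exact to double
precision.

### FitzHugh–Nagumo and Hodgkin–Huxley

Both receive input through *static* synapses: each input spike adds one
causal kernel to the drive — a difference of exponentials
`K(t) = 2(e^(−t) − e^(−2t))` for FHN, a normalized alpha function
`K(t) = e·(t/τ_ex)·e^(−t/τ_ex)` (peak 1 at `t = τ_ex`) for HH. Kernels are
represented exactly by auxiliary linear ODE states incremented at spike
times (one decaying state per exponential; the alpha function uses a
decaying state feeding a second one). This is O(1) per step, avoids
history sums, and makes the drive bit-stable across runs.

Integration is piecewise between input spikes with scipy's adaptive RK45
(`rtol 1e-7 / atol 1e-9` for HH, `1e-8 / 1e-10` for FHN by default; the
response-curve drivers use `1e-6 / 1e-8` for FHN, which the
tolerance-halving test shows is already well inside the 0.01-time-unit
spike-time stability requirement). Output spikes are located by the
integrator's event detection as upward crossings of a detection threshold,
then pruned by a refractory time.

Spike detection is not part of the model definition and had to be chosen:

* HH — upward crossing of 0 mV, refractory 1 ms. Full sodium spikes
  overshoot 0 mV by tens of mV; subthreshold synaptic depolarisations from
  a −65 mV rest never reach it.
* FHN — upward crossing of V = 0.5 (midway between the excitation
  threshold `a = 0.139` and the spike peak near 1), refractory 5 time
  units. The cubic model generates graded "spikes of different amplitudes"
  in transition regions; the midway threshold deliberately excludes the
  small humps, and the reference points (a clean 4:1 band; irregular
  transition dynamics) validate the choice.

HH units are mV/ms/µA·cm⁻²; FHN is dimensionless. The two are never mixed:
every `SpikeTrain` carries a unit tag and operations combining trains
require matching tags. HH rates are therefore in spikes/ms (0.17 = 170 Hz).

## Synthetic inputs

* **Periodic** — events at `t0 + k·T`; the baseline stimulus for all
  response curves.
* **Gamma-jittered** — renewal process with gamma-distributed intervals,
  shape `α` and rate `λ = α·λ_in`, so the mean interval is `1/λ_in` and the
  relative interval jitter is `1/√α`. The robustness analyses use `α = 100`
  (10% jitter) as the stated moderate-jitter condition; `α = 1` recovers a
  Poisson process. One explicitly seeded generator per call; identical
  specs give bit-identical trains.
* **Sweep** — ten-fold slow rate increase. The schedule is not specified
  anywhere beyond "slowly increases ten-fold"; we chose rate linear in time,
  stepped by the instantaneous inverse rate (`t_{m+1} = t_m + 1/rate(t_m)`),
  as the simplest scheme consistent with a slow sweep. Sweep reproductions
  are qualitative only.

First events sit at `t = 0` by convention; all consumers accept `t = 0`.

What the generators do **not** emulate: correlated (non-renewal) input
statistics, deliberately skipped spikes, amplitude variability, and any
biological heterogeneity or intrinsic noise. A green jitter-robustness test
therefore establishes robustness to *timing* jitter of a renewal type only
— it says nothing about correlated inputs or noisy spike generation.

## Rate estimation and locking labels

* Output rate: `λ_out = (N − 1)/span`, `span` = time from first to last
  output spike. Exact on periodic trains for any `N ≥ 2`; fewer than two
  spikes is reported as silent (rate 0).
* Error bound: miscounting one interval over a window of length `Δt`
  shifts the rate by at most `1/Δt`; expressed relative to the rate this is
  the printed bound `|Δf|/f ≤ 1/(f·Δt)` — 1% once 100 spikes are counted.
  `simulated_error_bound` returns the relative bound; response curves store
  the absolute bar `rate × bound = 1/span`.
* Sweep-protocol error estimate for fixed-count stimulation
  (50 input spikes per sweep): `e = (λ_in − λ_out)/50`, zero under 1:1
  locking; the divisor is exposed as a parameter.
* Locking classification: a rational rate ratio alone is insufficient — a
  randomly thinned train matches one by chance. A response is labelled
  `n:m` only if the sequence of input-spike counts between consecutive
  output spikes is periodic with period `m` (at least two full cycles
  observed), sums to `n` per cycle, and the measured rates agree with
  `λ_out = (m/n)·λ_in` within twice the combined error bars. Candidates are
  searched lowest order first (smallest `n + m`, ties toward smaller `n`),
  so a 2:1 response is never reported as 4:2. The count-sequence criterion
  is invariant under joint time rescaling and under input jitter that the
  output tracks, which is why a jittered-but-locked LIF still classifies
  as `ñ:1`. There is no universally agreed quantitative definition of
  "irregular"; here it is the complement of the locked test, validated
  against the reference points (3:1 at 170 Hz, irregular at 140.2 Hz).
* Non-monotonicity detection: maximal runs of grid steps where the output
  rate drops by more than the two points' error bars (plus an optional
  user tolerance). On closed-form curves every detected decrease is a
  single-step jump; under jitter the same mechanism yields multi-step
  finite downward slopes.

## Stationarity and transients

The resource variable converges to its fixed point exponentially from any
initial condition, so the LIF drivers discard `20·max(τ, μ)` before
counting (a package choice; no discard rule is stated for the original
simulated curves). Runs extend until ≥ 100 output spikes are counted
(≤ 1% relative error); a system producing no output within 5000 input
events after the transient is declared silent. ODE response-curve points
discard the first 10% of each run, at least 200 ms (HH) / 200 time units
(FHN).

## Grid and scale choices

Published axis ranges are not available in the extracted sources, so rate
ranges were fixed by exploration and then frozen: the slow-recovery LIF
curve on λ_in ∈ (0, 3] (only downward jumps; saturation near 0.3), the
equal-timescale curve on (0, 6] — its downward jumps only begin above
λ_in ≈ 3.5, below which the silent→5→4 onset produces the upward jumps —
the FHN curve on [0.005, 0.08] (1:1 through n:1 bands with the 4:1 band
near 0.04), the HH curve on [100, 250] Hz, and the silent-onset set on
[0.1, 8] (onset near λ_in ≈ 0.4). ODE grids (25 points) and per-point
durations (≈ 2–4 s of model time) are reduced relative to
publication-resolution sweeps to keep the full suite under a minute of ODE
time; the locking bands and decreasing regions are insensitive to this.

## Known limitations

* The FHN/HH locking classifier needs at least two full n:m cycles after
  the transient; very high-order locking (large m) on short runs falls back
  to "irregular".
* Exactly at a critical input rate the ceiling convention decides the
  locking integer; adjacent rates are unaffected (measure-zero set).
* The exact event-driven path covers the LIF model only; FHN/HH accuracy is
  set by integrator tolerances (spike times stable to < 0.01 ms under
  tolerance halving at the reference points).
* Inhibitory inputs (`c < 0`) are representable but untested and out of
  scope, as are facilitating synapses, networks, and intrinsic noise.
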
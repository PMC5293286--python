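# Methods

## Model

The network encodes a `J`-dimensional target `x(t)` — the drive `s(t)`
convolved with `exp(-λt)` — in the linear read-out `x̂ = wᵀ r` of leaky-
filtered spike trains.  Spiking follows from greedy minimization of
`E(t) = ‖x − x̂‖² + ν Σ r_i + μ Σ r_i²`: neuron *i* fires when its
membrane potential, the projected coding error `V_i = w_i·(x − x̂) − μ r_i`,
exceeds `‖w_i‖²/2 + μ/2 + ν/2`.  Differentiating gives the
integrate-and-fire form

    dV/dt = −λV + w s(t) − Φ o(t − delay) − μ o(t) + σ η(t),   Φ = w wᵀ.

Assumptions inherited from this derivation: the same filter `exp(-λt)` is
used for the signal, the rates and the read-out (fast currents only — slow
currents such as NMDA are out of scope); weights are fixed (no plasticity);
delays are homogeneous.

A note on the threshold: one printed form of the firing rule carries
`Σ w_ij²` without the factor ½, but the derivation (a spike is beneficial
iff `w_i·(x − x̂) > ‖w_i‖²/2` plus cost terms) fixes the ½; that form is
used throughout.

## Discretization and numerics

- **Time base.** Everything internal is in seconds; rates in Hz.  The
  membrane-noise standard deviation is accepted in the per-millisecond
  units common in this literature and converted at the config boundary
  (`σ_s = σ_ms·√1000`), so the per-step increment is
  `σ_ms·√(dt in ms)·N(0,1)` (Euler–Maruyama, independent across neurons).
- **Membrane integration.** Forward Euler at `dt = 0.1 ms` (default), so
  threshold crossings and resets are resolved step by step.  Signals,
  rates and read-outs use the exact exponential update
  `y[t+1] = y[t]·e^{−λdt} + input·dt` (unit impulses for spikes), which is
  unconditionally stable.  The mismatch between the two schemes is first
  order: `membrane_consistency_residual` verifies on noiseless, zero-delay
  runs that `V − (w(x − x̂) − μr)` is O(dt) and halves when dt halves.
- **Delay semantics.** The lateral part of `−Φ o` acts `delay` steps late;
  the diagonal (the neuron's own reset) and the `−μ` adaptation act
  immediately, because the reset is the neuron's own mechanism, not a
  synapse.  A `self_delay` switch routes the self terms through the delay
  buffer for users who prefer the fully delayed reading; the default is
  documented here because the source derivation does not fix it.
- **Within-step spike resolution.**  In *delayed* mode every suprathreshold
  neuron fires in the step (this is what produces population-wide
  synchronization).  In *instantaneous* mode spikes are resolved one at a
  time, largest threshold violation first, with the full recurrent update
  applied before re-testing; ties are broken uniformly at random.  This
  realizes the greedy descent exactly: each resolved spike strictly lowers
  `E(t)` (property-tested).
- **Spike failure.** One Bernoulli(`p_spike`) draw per suprathreshold
  neuron per step; on failure no reset is applied, so the membrane stays
  near threshold and usually fires within a few steps.
- **Forced spikes.** The minimal-model episodes start from a noise-driven
  threshold crossing.  A forced spike therefore places the membrane at the
  cost-free threshold `‖w‖²/2` (the noise-initiation condition carries no
  cost term) and fires unconditionally.  The discrete two-neuron episode
  has two delays between a neuron's spike and the return excitation, so
  the exact sustained-firing bound is `ν < a²(1 − e^{−2λd})`, within
  O(ε²) of the closed-form `2a²ε` window boundary.
- **Degenerate inputs.** Gamma fitting of inter-burst intervals is refused
  below 10 intervals or at zero variance (with an informative status);
  CV2 excludes neurons with fewer than 3 spikes and flags the all-sparse
  case; synchrony and S-MUA flag empty rasters.

## Default parameters (study conditions)

| parameter | default | rationale |
|---|---|---|
| leak λ | 4 Hz | decoder/membrane time constant of the small worked examples; kept network-wide |
| dt | 0.1 ms | resolves the 1 ms delay into 10 steps |
| delay | 1 ms (2 ms topographic) | constant, identical for all synapses |
| noise σ | 0.25 ms⁻¹ | the level at which quiescent Up states appear without swamping thresholds |
| p_spike | 1.0 (0.3 where failure is studied) | failure softens within-burst synchrony, does not trigger Up states |
| input λ_input | 2 Hz | slow signal relative to λ |
| input amplitude | 2000 | keeps the 100-neuron network in the active tracking regime over the whole default cost grid (target-signal sd ≈ 180 in units of the N(0,1) weights); results are insensitive to the drive strength over a wide range |
| cost grid | ν, μ ∈ {0, 2, 4, 8, 12} | brackets the synchronized, the efficient and the over-suppressed regimes |
| sweep size | N = 100, J = 3, 4 s/cell, 3 repeats | scaled down from the reference 400-neuron, long-trial setting |
| Up-state criterion | ≥ 20% of neurons with a spike in a trailing window of one delay | the fraction is the standard operational criterion; results are qualitatively robust to it |
| MUA decay λ_D | 50 Hz | short memory that tracks fast population-rate fluctuations |
| Gamma fit | MLE (`scipy.stats.gamma`, location fixed at 0) | method-of-moments start internally |
| Epanechnikov bandwidth | `2.345·σ̂·n^{−1/5}` | plug-in rule for this kernel; overridable |

## What the synthetic drive does and does not emulate

The smoothed-white-noise drive reproduces the defining features of the
study conditions: stationary, Gaussian, uncorrelated across dimensions,
with a single smoothing time constant.  It does not emulate naturalistic
stimulus statistics (heavy tails, cross-channel correlations,
non-stationarity), so passing tests demonstrate the network's
self-correction and efficiency structure under idealized drive, not
performance on natural signals.  The circular bump drive likewise uses a
single smoothed-noise trajectory; real topographic inputs would carry
multiple objects and occlusions.

## Efficiency measure

`⟨error⟩` is the time-averaged L1 distance between signal and read-out per
dimension, normalized by the across-neuron mean weight norm (so the
measure is invariant to a global rescaling of `w`).  `⟨cost⟩` is the
population firing rate in spikes/second, and
`Total = α⟨error⟩ + β⟨cost⟩` with `α = β = 1` by default.

Two properties of this convention deserve note.  First, with rates in Hz
the Total is numerically dominated by `⟨cost⟩` wherever the network fires
at hundreds of Hz; the structure that matters — catastrophic zero-cost
cells, steep improvement with moderate costs, slow change beyond — is
unchanged, and `⟨error⟩` on its own exhibits a genuine interior minimum
along ν (tested).  Second, had the rate been expressed per millisecond
(the natural unit of the noise term), error and cost would be of the same
order and the Total itself would rise beyond the optimum; the package
keeps seconds/Hz as its single time base and asserts the optimum as
"requires non-zero costs of both kinds" rather than as a strict interior
point of an unbounded grid.

## Up-state statistics

The spike-triggered multi-unit activity uses the causal kernel
`exp(-λ_D t)` and a ±100 ms lag window; the shuffle term pairs each
neuron's spikes with the MUA of the *next* trial (circular shift), and the
corrected, neuron-averaged profile is normalized by the total spike count.
Because recruitment through delayed synapses is causal, the fine-grained
(0.1 ms) argmax of the corrected profile sits a few synaptic delays
*after* zero in strongly synchronized regimes — the profile is still
rising through the burst ramp — while a raster whose bursts are single
volleys peaks exactly at zero (unit-tested).  At the resolution of the
±100 ms window the profile is a single central peak at zero lag, and that
is the property the acceptance test asserts.

## Known limitations

- The absolute coordinates of the optimum (the particular optimal (ν, μ)
  values) depend on the full parameter set of the original study
  conditions, which is not available; the package reproduces the existence
  and ordering properties of the phenomena at scaled-down sizes.
- Forward Euler limits accuracy to first order in dt; event-driven exact
  integration is out of scope.
- Heterogeneous delays, conductance synapses, plastic weights and slow
  currents are not modelled.
- The raising-ν-never-increases-spike-count property is asserted on
  frozen noise for the default conditions; it is an empirical regularity
  of this regime, not a theorem — chaotic rasters can in principle violate
  it cell by cell.
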
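# spikepc — predictive-coding spiking networks

`spikepc` simulates networks of leaky integrate-and-fire neurons that are
*derived*, rather than postulated: every spike is fired only if it reduces
a coding objective, so the network as a whole tracks a target signal with
its linear read-out and automatically corrects its own mistakes.  The
package is aimed at computational neuroscientists studying the relation
between coding efficiency and spontaneous population events (Up/Down
states) in balanced networks.

## The model

A population of `N` neurons with decoding weights `w_i ∈ R^J` represents a
`J`-dimensional signal `x(t)` (the input `s(t)` convolved with an
exponential filter `exp(-λt)`) through the read-out

    x̂_j(t) = Σ_i w_ij r_i(t),       r_i = spike train ⊛ exp(-λt).

Greedy minimization of the objective

    E(t) = ‖x(t) − x̂(t)‖² + ν Σ_i r_i(t) + μ Σ_i r_i(t)²

yields leaky integrate-and-fire dynamics in which the membrane potential
is the projected coding error, `V_i = w_i·(x − x̂) − μ r_i`:

    dV_i/dt = −λ V_i + w_i·s(t) − [Φ o(t − delay)]_i − μ o_i(t) + σ η_i(t)

with recurrent connectivity `Φ = w wᵀ` and firing rule
`V_i > ‖w_i‖²/2 + μ/2 + ν/2`.  The linear cost ν raises all thresholds
(penalizing population rate); the quadratic cost μ additionally deepens
the after-spike hyperpolarization (spike-triggered adaptation).  With
synaptic delays and membrane noise, poorly chosen costs produce the
"ping-pong" effect — delayed mutual excitation between neurons of opposite
selectivity — whose population-wide form is a spontaneous Up state.

The toolkit contains:

- `network` — random all-to-all and topographic ON/OFF ring networks,
  thresholds, connectivity;
- `signals` — smoothed-white-noise drive, circular Gaussian-bump drive,
  exponential (leaky) filtering;
- `simulator` — delayed or instantaneous coupling, Euler–Maruyama membrane
  noise, spike-generation failure, forced-spike episodes, decoding,
  membrane-consistency diagnostics;
- `upstate` — MUA, shuffle-corrected spike-triggered MUA, Up-state
  detection (≥20% of neurons active within a window), inter-burst-interval
  Gamma fits, duration densities (Epanechnikov kernel), CV2, synchrony;
- `efficiency` — mean coding error ⟨error⟩, spike cost ⟨cost⟩
  (population rate), Total error `α⟨error⟩ + β⟨cost⟩`, and (ν, μ) sweeps
  locating the optimal working regime.

## Worked example

The two-neuron minimal model makes every spike interpretable
(`examples/02_minimal_pair.py`):

```text
10:1 weights -> corrective spikes of neuron 2: 10 (estimate back at origin after 1.9 ms)
nu = 0.5000 (inside window ): spikes per neuron = 1, 1 over 300 ms
nu = 0.0020 (below window): spikes per neuron = 150, 150 over 300 ms
```

A forced spike of a neuron whose weight is 10× its antagonist's sends the
read-out far from the origin; exactly 10 spikes of the small-weight neuron
bring it back.  With antisymmetric weights `(a, −a)`, a linear cost inside
the window `2a²ε < ν < a²` (with `ε = 1 − e^{−λ·delay}`) permits the one
corrective spike and then silence; below the window each corrective spike
re-excites the other neuron and the pair fires alternately forever — one
spike per neuron every two delays (150 each in 300 ms).

At network scale (`examples/03_up_states.py`), a quiescent noisy network
with μ = 5 shows spontaneous Up states whose frequency falls with ν
(0.80/s at ν = 0, zero at ν = 6) while the read-out during Up states keeps
oscillating around zero — spontaneous activity is orthogonal to the
stimulus representation.  `examples/04_efficiency_sweep.py` sweeps the
cost plane: zero-cost cells are catastrophic (≈ 5·10⁵ total error from
ping-pong synchronization), the optimum needs non-zero costs of both
kinds, Up states vanish there, and spiking at the optimum is at or below
Poisson irregularity (CV2 ≈ 0.6).

A thin CLI wraps the same functionality:

```bash
spikepc simulate --quiescent --nu 4 --mu 5 --duration 5 --out run/
spikepc sweep --out sweep/
spikepc stats --spikes run/spikes.csv --n-neurons 100
spikepc demo --out demo/
```

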
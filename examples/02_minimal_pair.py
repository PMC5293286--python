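"""Two-neuron minimal model: error-correcting versus ping-pong spiking.

A forced spike of one neuron creates a prediction error that the neuron of
opposite selectivity corrects.  With weights in ratio 10:1 the correction
takes exactly 10 spikes.  With antisymmetric weights (a, -a) the linear
cost decides what happens after the single corrective spike: inside the
window 2 a^2 eps < nu < a^2 (eps = 1 - exp(-lambda * delay)) the pair
falls silent; below it the delayed mutual excitation sustains alternating
firing — the ping-pong effect that underlies Up states.
"""

import numpy as np

from spikepc import CostParams, NetworkSpec, SimConfig, quiescent_input, simulate

dt, lam, delay = 1e-4, 4.0, 1e-3

# --- 10:1 weight ratio: ten corrective spikes ---------------------------
spec = NetworkSpec(w=np.array([[1.0], [-0.1]]))
cfg = SimConfig(dt=dt, leak_rate=0.05, delay=delay, coupling_mode="delayed")
res = simulate(spec, quiescent_input(1, 0.05, dt), CostParams(0, 0), cfg,
               forced_spikes=[(0, 0)])
back = np.nonzero(np.abs(res.estimate[0]) <= 0.05)[0]
back = back[back > 0][0]
print(f"10:1 weights -> corrective spikes of neuron 2: "
      f"{res.o[1, :back + 1].sum()} (estimate back at origin after "
      f"{back * dt * 1000:.1f} ms)")

# --- antisymmetric weights: the linear-cost window -----------------------
a = 1.0
eps = 1 - np.exp(-lam * delay)
for nu, label in [(0.5, "inside window "), (a**2 * eps / 2, "below window")]:
    spec2 = NetworkSpec(w=np.array([[a], [-a]]))
    cfg2 = SimConfig(dt=dt, leak_rate=lam, delay=delay, coupling_mode="delayed")
    r = simulate(spec2, quiescent_input(1, 0.3, dt), CostParams(nu=nu), cfg2,
                 forced_spikes=[(0, 0)])
    print(f"nu = {nu:.4f} ({label}): spikes per neuron = "
          f"{r.o[0].sum()}, {r.o[1].sum()} over 300 ms")
# Inside the window: 1 forced + 1 corrective spike, then silence.
# Below it: sustained alternation, one spike per neuron every 2 ms.
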
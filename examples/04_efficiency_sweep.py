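"""Coding efficiency over the (nu, mu) cost plane.

Sweeps the spike-cost parameters of a delayed noisy network driven by
smoothed white noise and reports the mean coding error (weight-normalized
L1 distance), the spike cost (population rate) and their sum,
the Total error.  Zero costs are catastrophic (ping-pong synchronization);
the optimum needs non-zero costs of both kinds.
"""

import numpy as np

from spikepc import (
    CostParams, SimConfig, build_random_network, compute_cv2, cost_sweep,
    simulate, smoothed_white_noise,
)

dt = 1e-4
spec = build_random_network(100, 3, rng_seed=42)
cfg = SimConfig(dt=dt, leak_rate=4.0, delay=1e-3, noise_sd=0.25,
                coupling_mode="delayed", record_v=False)


def gen(seed):
    return smoothed_white_noise(3, 2.0, dt, 2.0, 2000.0, seed)


grid = [0.0, 4.0, 12.0]
surf = cost_sweep(spec, gen, cfg, nu_grid=grid, mu_grid=grid,
                  n_repeats=2, rng_seed=17)
print("Total error over the (nu, mu) grid (rows: nu, cols: mu):")
for i, nu in enumerate(grid):
    row = "  ".join(f"{surf.total[i, j]:10.1f}" for j in range(len(grid)))
    print(f"  nu={nu:4.1f}:  {row}")
nu_opt, mu_opt = surf.optimum
print(f"optimum: nu = {nu_opt}, mu = {mu_opt}, "
      f"total = {surf.optimum_value:.1f} "
      f"(error {surf.error[surf.optimum_indices]:.2f} + "
      f"cost {surf.cost[surf.optimum_indices]:.1f} Hz)")
print(f"Up-state frequency at the optimum: "
      f"{surf.upstate_freq[surf.optimum_indices]:.2f}/s")

# irregularity at the optimum: near- or sub-Poisson spiking
inp = smoothed_white_noise(3, 6.0, dt, 2.0, 2000.0, 99)
res = simulate(spec, inp, CostParams(nu=nu_opt, mu=mu_opt),
               SimConfig(dt=dt, leak_rate=4.0, delay=1e-3, noise_sd=0.25,
                         coupling_mode="delayed", record_v=False, rng_seed=98))
print(f"mean CV2 at the optimum: {compute_cv2(res.o, dt=dt).mean:.2f} "
      f"(1 = Poisson)")
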
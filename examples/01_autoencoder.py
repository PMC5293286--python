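"""Single-neuron auto-encoder: greedy error minimization as a reset rule.

One neuron with weight w = 1 tracks a smoothed-noise signal.  Its membrane
potential equals the coding error x - xhat; whenever the error exceeds
w^2/2 the neuron spikes, which pulls the estimate up by w.
"""

import numpy as np

from spikepc import (
    CostParams, NetworkSpec, SimConfig, coding_error, simulate,
    smoothed_white_noise, spike_cost,
)

dt = 1e-4
spec = NetworkSpec(w=np.array([[1.0]]))
inp = smoothed_white_noise(1, 5.0, dt, smoothing_rate=2.0, amplitude=30.0,
                           rng_seed=0)
cfg = SimConfig(dt=dt, leak_rate=4.0, delay=0.0, coupling_mode="instantaneous")
res = simulate(spec, inp, CostParams(0.0, 0.0), cfg)

err = coding_error(res)
print(f"spikes fired          : {res.total_spikes}")
print(f"firing rate           : {spike_cost(res):.1f} Hz")
print(f"mean |x - xhat|       : {err:.3f}  (weight-normalized)")
print(f"max membrane potential: {res.v.max():.3f}  (threshold = 0.5)")
# The error never exceeds the threshold for long: a single positive-weight
# neuron can only correct from below, so the residual error is set by how
# often the signal outruns one spike's worth of correction.
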
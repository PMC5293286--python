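"""Numba-compiled integration loops for the spiking network.

Two coupling modes are implemented.  In *delayed* mode every neuron whose
potential exceeds its threshold fires within the same step; the lateral
part of the recurrent interaction (and optionally the self term) is
applied ``d_steps`` later, while by default the neuron's own reset acts
immediately.  In *instantaneous* mode spikes within a step are resolved
one at a time, largest threshold violation first, with the full recurrent
update applied before re-testing; this realizes the greedy one-spike-at-
a-time minimization of the coding error.

Spike-generation failure: each suprathreshold neuron draws a Bernoulli
with success probability ``p_spike`` (once per step); on failure no reset
is applied and the potential stays near threshold.

Forced spikes emulate a noise-driven threshold crossing: the membrane is
placed at the cost-free threshold ``phi_ii / 2`` and the neuron fires
unconditionally.
"""

import numba
import numpy as np

NO_TRACE = np.zeros((1, 1))


@numba.njit(cache=True)
def run_delayed(
    F,            # (N, T) feed-forward current w @ s
    phi,          # (N, N) symmetric connectivity
    thres,        # (N,) firing thresholds
    lam,          # leak rate, 1/s
    dt,           # step, s
    d_steps,      # synaptic delay in steps (>= 1 for true delayed coupling)
    mu,           # quadratic cost (self hyperpolarization per spike)
    sigma_step,   # noise sd per step (already scaled by sqrt(dt))
    p_spike,      # spike-generation probability
    seed,         # RNG seed for membrane noise and spike failures
    V0,           # (N,) initial potentials
    forced_steps, # (K,) int64 steps at which spikes are forced
    forced_ids,   # (K,) int64 neuron ids of forced spikes
    self_delay,   # if True the reset/adaptation also goes through the delay
    noise,        # (N, T) externally frozen noise increments, or (1, 1)
    use_noise,    # whether to use the frozen noise array
    record_v,     # whether to store the full V trace
):
    N, T = F.shape
    np.random.seed(seed)
    V = V0.astype(np.float64).copy()
    o = np.zeros((N, T), dtype=np.uint8)
    vtrace = np.zeros((N, T)) if record_v else np.zeros((1, 1))
    nf = forced_steps.shape[0]

    for t in range(T):
        # forward-Euler leak + feed-forward
        for i in range(N):
            V[i] += dt * (-lam * V[i] + F[i, t])
        if use_noise:
            for i in range(N):
                V[i] += noise[i, t]
        elif sigma_step > 0.0:
            xi = np.random.standard_normal(N)
            for i in range(N):
                V[i] += sigma_step * xi[i]

        # delayed recurrent input from spikes d_steps ago
        td = t - d_steps
        if td >= 0:
            for k in range(N):
                cnt = o[k, td]
                if cnt > 0:
                    c = float(cnt)
                    row = phi[k]  # symmetric: column k == row k
                    for i in range(N):
                        V[i] -= row[i] * c
                    if self_delay:
                        V[k] -= mu * c
                    else:
                        V[k] += row[k] * c  # self term was applied at spike time

        # forced spikes: place membrane at the cost-free threshold and fire
        for f in range(nf):
            if forced_steps[f] == t:
                i = forced_ids[f]
                V[i] = 0.5 * phi[i, i]
                o[i, t] += 1
                if not self_delay:
                    V[i] -= phi[i, i] + mu

        # threshold test; every suprathreshold neuron may fire this step
        for i in range(N):
            if V[i] > thres[i]:
                if p_spike >= 1.0 or np.random.random() < p_spike:
                    o[i, t] += 1
                    if not self_delay:
                        V[i] -= phi[i, i] + mu

        if record_v:
            for i in range(N):
                vtrace[i, t] = V[i]

    return o, vtrace, V


@numba.njit(cache=True)
def run_instantaneous(
    F, phi, thres, lam, dt, mu, sigma_step, p_spike, seed, V0,
    forced_steps, forced_ids, noise, use_noise, record_v,
):
    N, T = F.shape
    np.random.seed(seed)
    V = V0.astype(np.float64).copy()
    o = np.zeros((N, T), dtype=np.uint8)
    vtrace = np.zeros((N, T)) if record_v else np.zeros((1, 1))
    nf = forced_steps.shape[0]
    failed = np.zeros(N, dtype=np.uint8)
    max_spikes = 64 * N  # guard against runaway within-step cascades

    for t in range(T):
        for i in range(N):
            V[i] += dt * (-lam * V[i] + F[i, t])
        if use_noise:
            for i in range(N):
                V[i] += noise[i, t]
        elif sigma_step > 0.0:
            xi = np.random.standard_normal(N)
            for i in range(N):
                V[i] += sigma_step * xi[i]

        for f in range(nf):
            if forced_steps[f] == t:
                i = forced_ids[f]
                V[i] = 0.5 * phi[i, i]
                o[i, t] += 1
                row = phi[i]
                for k in range(N):
                    V[k] -= row[k]
                V[i] -= mu

        # resolve spikes greedily: largest violation first, immediate update
        for i in range(N):
            failed[i] = 0
        n_fired = 0
        while n_fired < max_spikes:
            best = -1
            best_v = 0.0
            n_tied = 0
            for i in range(N):
                if failed[i] == 0:
                    viol = V[i] - thres[i]
                    if viol > 0.0:
                        if best < 0 or viol > best_v + 1e-15:
                            best = i
                            best_v = viol
                            n_tied = 1
                        elif viol > best_v - 1e-15:
                            # tie: reservoir-sample uniformly among ties
                            n_tied += 1
                            if np.random.random() < 1.0 / n_tied:
                                best = i
                                best_v = viol
            if best < 0:
                break
            if p_spike < 1.0 and np.random.random() >= p_spike:
                failed[best] = 1  # failure: no reset, ineligible this step
                continue
            o[best, t] += 1
            n_fired += 1
            row = phi[best]
            for k in range(N):
                V[k] -= row[k]
            V[best] -= mu

        if record_v:
            for i in range(N):
                vtrace[i, t] = V[i]

    return o, vtrace, V
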
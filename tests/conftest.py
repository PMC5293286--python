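import numpy as np
import pytest

from spikepc import CostParams, NetworkSpec, SimConfig, quiescent_input, simulate


def pair_network(w1: float, w2: float) -> NetworkSpec:
    """Two-neuron network with scalar weights (w1, w2) on one signal."""
    return NetworkSpec(w=np.array([[w1], [w2]]))


@pytest.fixture(scope="session")
def small_random_spec():
    from spikepc import build_random_network

    return build_random_network(30, 2, rng_seed=3)


def run_quiescent_pair(
    w1: float,
    w2: float,
    nu: float = 0.0,
    mu: float = 0.0,
    leak_rate: float = 4.0,
    delay: float = 1e-3,
    duration: float = 0.2,
    dt: float = 1e-4,
):
    """Forced-spike episode of the two-neuron minimal model, no drive/noise."""
    spec = pair_network(w1, w2)
    cfg = SimConfig(dt=dt, leak_rate=leak_rate, delay=delay,
                    coupling_mode="delayed")
    inp = quiescent_input(1, duration, dt)
    return simulate(spec, inp, CostParams(nu=nu, mu=mu), cfg,
                    forced_spikes=[(0, 0)])
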
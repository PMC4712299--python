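import numpy as np
import pytest

from spikesim.network import NetworkSpec, add_population, connect_all_to_all
from spikesim.neurons import default_params


@pytest.fixture
def lif_pair():
    """Two LIF neurons, mutually connected, non-plastic."""
    net = NetworkSpec(max_delay_ms=4)
    pop = add_population(net, "pair", 2, "lif", default_params("lif"))
    connect_all_to_all(net, pop, pop, weight=5.0, delay=1)
    return net, pop


@pytest.fixture
def small_plastic_net():
    """Ten LIF neurons, all-to-all plastic synapses (90 rows)."""
    net = NetworkSpec(max_delay_ms=1, w_min=0.0, w_max=1.0)
    pop = add_population(net, "p", 10, "lif", default_params("lif"))
    connect_all_to_all(net, pop, pop, weight=0.5, delay=1, plastic=True)
    net.synapses.sort_by_pre()
    return net, pop


def poisson_trains(n_neurons, duration_ms, rate_hz, rng):
    """Per-step spiker lists for independent Poisson-like (Bernoulli) trains."""
    p = rate_hz / 1000.0
    spikes = rng.random((duration_ms, n_neurons)) < p
    return [np.flatnonzero(spikes[t]) for t in range(duration_ms)]
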
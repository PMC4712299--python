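import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spikesim.network import (NetworkSpec, add_population, connect_all_to_all,
                              connect_fixed_fanout, grid_positions,
                              load_network, sample_gaussian_targets,
                              save_network, substream, toroidal_distance,
                              validate_network)
from spikesim.neurons import default_params


def _net():
    return NetworkSpec(max_delay_ms=20, w_min=0.0, w_max=10.0)


def test_population_indices_are_contiguous():
    net = _net()
    a = add_population(net, "exc", 800, "izhikevich", default_params("izhikevich"))
    b = add_population(net, "inh", 200, "izhikevich",
                       default_params("izhikevich", a=0.1, d=2.0), "inh")
    assert (a.start, a.stop) == (0, 800)
    assert (b.start, b.stop) == (800, 1000)
    assert net.n_neurons == 1000


@pytest.mark.parametrize("kwargs, match", [
    (dict(model_id="nope", params={}), "unknown neuron model"),
    (dict(model_id="aeif", params={"C": 281.0}), "missing"),
    (dict(model_id="lif", params=dict(default_params("lif"), bogus=1)), "extra"),
    (dict(model_id="lif", params=default_params("lif"), size=0), ">= 1"),
])
def test_add_population_validation(kwargs, match):
    net = _net()
    args = dict(size=5, sign="exc")
    args.update(kwargs)
    with pytest.raises((KeyError, ValueError), match=match):
        add_population(net, "p", args["size"], args["model_id"], args["params"],
                       args["sign"])


def test_fixed_fanout_outdegree_exact_and_no_self():
    net = _net()
    pop = add_population(net, "p", 50, "lif", default_params("lif"))
    n = connect_fixed_fanout(net, pop, np.arange(50), fanout=10,
                             weight_sampler=lambda r, s: np.ones(s),
                             delay_sampler=lambda r, s: r.integers(1, 21, s),
                             plastic=True, rng_seed=3)
    assert n == 500
    assert np.all(net.synapses.out_degrees(50) == 10)
    assert not np.any(net.synapses.pre == net.synapses.post)
    # no multi-edges: targets drawn without replacement
    pairs = net.synapses.pre * 50 + net.synapses.post
    assert np.unique(pairs).size == pairs.size


def test_fixed_fanout_determinism_and_edge_cases():
    def build(seed):
        net = _net()
        pop = add_population(net, "p", 20, "lif", default_params("lif"))
        connect_fixed_fanout(net, pop, np.arange(20), 5,
                             lambda r, s: r.uniform(0, 1, s),
                             lambda r, s: r.integers(1, 21, s),
                             False, seed)
        return net.synapses

    a, b = build(7), build(7)
    for col in ("pre", "post", "weight", "delay_ms"):
        assert np.array_equal(getattr(a, col), getattr(b, col))
    net = _net()
    pop = add_population(net, "p", 20, "lif", default_params("lif"))
    assert connect_fixed_fanout(net, pop, np.arange(20), 0,
                                lambda r, s: np.ones(s),
                                lambda r, s: np.ones(s), False, 0) == 0
    with pytest.raises(ValueError, match="exceeds"):
        connect_fixed_fanout(net, pop, np.arange(5), 5,
                             lambda r, s: np.ones(s),
                             lambda r, s: np.ones(s), False, 0)


def test_all_to_all_counts():
    net = _net()
    a = add_population(net, "a", 2, "aeif", default_params("aeif"))
    assert connect_all_to_all(net, a, a, 0.1, 1) == 2  # mutual pair
    net = _net()
    b = add_population(net, "b", 7, "lif", default_params("lif"))
    assert connect_all_to_all(net, b, b, 0.1, 1) == 7 * 6
    net = _net()
    c = add_population(net, "c", 3, "lif", default_params("lif"))
    d = add_population(net, "d", 2, "lif", default_params("lif"))
    assert connect_all_to_all(net, c, d, 0.1, 1) == 6


def test_toroidal_distance_examples():
    assert toroidal_distance((0, 0), (255, 0), (256, 256)) == 1.0
    assert toroidal_distance((13, 7), (13, 7), (256, 256)) == 0.0
    assert np.isclose(toroidal_distance((0, 0), (128, 128), (256, 256)),
                      128 * np.sqrt(2))
    with pytest.raises(ValueError):
        toroidal_distance((0, 0), (256, 0), (256, 256))


coords = st.tuples(st.integers(0, 31), st.integers(0, 31))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(coords, coords, coords)
def test_toroidal_distance_is_a_metric(p, q, r):
    dims = (32, 32)
    dpq = toroidal_distance(p, q, dims)
    assert dpq == toroidal_distance(q, p, dims)          # symmetry
    assert (dpq == 0.0) == (p == q)                      # identity
    assert dpq <= toroidal_distance(p, r, dims) + toroidal_distance(r, q, dims) + 1e-9


def _torus_net(dims):
    net = NetworkSpec(max_delay_ms=16)
    add_population(net, "p", dims[0] * dims[1], "lif", default_params("lif"),
                   positions=grid_positions(dims))
    return net


def test_gaussian_sampling_mean_distance_grows_with_sigma():
    dims = (64, 64)
    net = _torus_net(dims)
    pos = net.positions()
    for seed in (0, 1, 2):
        means = []
        for sigma in (4.0, 32.0):
            rng = substream(seed, f"s{sigma}")
            d_all = []
            for _ in range(30):
                _, d = sample_gaussian_targets(0, pos, dims, sigma, 20, rng)
                d_all.append(d)
            means.append(np.concatenate(d_all).mean())
        assert means[0] < means[1]


def test_gaussian_sampling_tight_sigma_stays_local():
    dims = (64, 64)
    net = _torus_net(dims)
    rng = substream(5, "tight")
    _, d = sample_gaussian_targets(0, net.positions(), dims, 0.75, 30, rng)
    assert d.max() < 6.0


def test_gaussian_sampling_matches_exhaustive_enumeration():
    """Fan-out-1 draws follow the normalized Gaussian-weight distribution.

    The oracle enumerates all candidate targets on the torus, computes
    P ∝ exp(-d²/2σ²) exactly, and a chi-square test compares 20,000 sampled
    distances against the enumerated distance distribution.
    """
    dims = (64, 64)
    sigma = 8.0
    net = _torus_net(dims)
    pos = net.positions()
    cand = np.arange(1, 64 * 64)
    d_cand = np.array([toroidal_distance(pos[0], pos[i], dims) for i in cand])
    p = np.exp(-0.5 * (d_cand / sigma) ** 2)
    p /= p.sum()
    # distance bins with enumerated expected mass >= ~1% each
    order = np.argsort(d_cand)
    cum = np.cumsum(p[order])
    n_bins = 15
    cut_idx = np.searchsorted(cum, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.concatenate([[0.0], np.sort(d_cand[order][cut_idx]), [d_cand.max() + 1]])
    expected_mass, _ = np.histogram(d_cand, bins=edges, weights=p)
    n_draws = 20_000
    rng = substream(11, "chisq")
    draws = np.empty(n_draws)
    for k in range(n_draws):
        _, d = sample_gaussian_targets(0, pos, dims, sigma, 1, rng)
        draws[k] = d[0]
    observed, _ = np.histogram(draws, bins=edges)
    keep = expected_mass > 0
    res = stats.chisquare(observed[keep], expected_mass[keep] * n_draws)
    assert res.pvalue > 1e-3


def test_bernoulli_distance_connector_expected_degree():
    from spikesim.network import connect_distance_bernoulli
    dims = (32, 32)
    net = _torus_net(dims)
    pop = net.populations[0]
    n = connect_distance_bernoulli(net, pop, sigma=6.0, n_syn_expected=20,
                                   weight_sampler=lambda r, s: np.ones(s),
                                   delay_rule=lambda d: np.ones(len(d)),
                                   dims=dims, rng_seed=4)
    deg = net.synapses.out_degrees(net.n_neurons)
    # expected out-degree 20; binomial fluctuation over 1024 neurons
    assert abs(deg.mean() - 20.0) < 0.5
    assert deg.std() > 0          # varying number of targets, unlike fixed fanout
    assert not np.any(net.synapses.pre == net.synapses.post)


def test_validate_network_reports_violations():
    net = _net()
    pop = add_population(net, "p", 5, "lif", default_params("lif"))
    net.synapses.append([0], [1], [0.5], [0], [True])     # delay 0
    net.synapses.append([1], [2], [99.0], [1], [True])    # above w_max
    net.synapses.append([2], [2], [0.5], [1], [False])    # self-connection
    report = validate_network(net)
    assert any("delay below 1 ms" in r for r in report)
    assert any("w_min" in r or "w_max" in r for r in report)
    assert any("self-connection" in r for r in report)


def test_validate_network_clean_on_valid_preset():
    from spikesim.experiments import build_polychronous_network
    net, _, _ = build_polychronous_network(seed=0)
    assert validate_network(net) == []


def test_network_serialization_roundtrip(tmp_path):
    net = _net()
    pop = add_population(net, "p", 6, "izhikevich", default_params("izhikevich"),
                         positions=grid_positions((3, 2)))
    connect_fixed_fanout(net, pop, np.arange(6), 2,
                         lambda r, s: r.uniform(0, 1, s),
                         lambda r, s: r.integers(1, 5, s), True, 1)
    save_network(net, tmp_path / "net")
    back = load_network(tmp_path / "net")
    assert back.n_neurons == net.n_neurons
    assert back.max_delay_ms == net.max_delay_ms
    for col in ("pre", "post", "weight", "delay_ms", "plastic"):
        assert np.array_equal(getattr(back.synapses, col), getattr(net.synapses, col))
    assert np.array_equal(back.populations[0].positions, pop.positions)
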
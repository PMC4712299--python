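import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import poisson_trains
from spikesim.network import NetworkSpec, add_population, connect_all_to_all
from spikesim.neurons import default_params
from spikesim.stdp import (PlasticityLedger, STDPConfig, make_delta_w_table,
                           nearest_neighbor_pairs, stdp_delta_w)

FIG_CFG = STDPConfig(A_plus=0.1, A_minus=0.12, tau_plus_ms=20.0,
                     tau_minus_ms=20.0, w_min=0.0, w_max=0.25)


# ---------------------------------------------------------------------------
# The update rule itself
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dt, expected", [
    (1e-9, 0.1),                       # potentiation limit at 0+
    (-1e-9, -0.12),                    # depression limit at 0-
    (10.0, 0.1 * np.exp(-0.5)),
    (-10.0, -0.12 * np.exp(-0.5)),
    (0.0, 0.0),
    (1e6, 0.0),
    (-1e6, 0.0),
])
def test_delta_w_values(dt, expected):
    assert np.isclose(stdp_delta_w(dt, FIG_CFG), expected, rtol=1e-6, atol=1e-12)


def test_delta_w_lookup_table_matches_analytic_formula():
    pot, dep = make_delta_w_table(FIG_CFG, window_ms=120)
    dts = np.arange(1, 121, dtype=float)
    assert np.array_equal(pot, stdp_delta_w(dts, FIG_CFG))
    assert np.array_equal(dep, stdp_delta_w(-dts, FIG_CFG))


# ---------------------------------------------------------------------------
# Nearest-neighbor pairing
# ---------------------------------------------------------------------------

def test_pairing_examples():
    assert nearest_neighbor_pairs([10], [5, 30]) == [(-5.0, "depression"),
                                                     (20.0, "potentiation")]
    assert nearest_neighbor_pairs([10, 40], [5, 30]) == [
        (-5.0, "depression"), (20.0, "potentiation"), (-10.0, "depression")]
    assert nearest_neighbor_pairs([1, 2, 3], []) == []
    with pytest.raises(ValueError, match="strictly increasing"):
        nearest_neighbor_pairs([5, 5], [1])


def _brute_force_pairs(pre, post, window=None):
    out = []
    for tp in pre:
        before = [t for t in post if t <= tp]
        after = [t for t in post if t > tp]
        if before:
            dt = max(before) - tp
            if window is None or -dt <= window:
                out.append((float(dt), "depression"))
        if after:
            dt = min(after) - tp
            if window is None or dt <= window:
                out.append((float(dt), "potentiation"))
    return out


spike_train = st.lists(st.integers(0, 500), min_size=0, max_size=40,
                       unique=True).map(sorted)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(spike_train, spike_train)
def test_pairing_equals_brute_force_enumeration(pre, post):
    assert nearest_neighbor_pairs(pre, post) == _brute_force_pairs(pre, post)
    assert (nearest_neighbor_pairs(pre, post, window_ms=30)
            == _brute_force_pairs(pre, post, window=30))


# ---------------------------------------------------------------------------
# Deferred ledger
# ---------------------------------------------------------------------------

def _feed(ledger, spikers_per_step):
    for t, ids in enumerate(spikers_per_step):
        ledger.record(ids, t)


def test_isolated_pre_spike_contributes_nothing(small_plastic_net):
    net, _ = small_plastic_net
    ledger = PlasticityLedger(net.synapses, STDPConfig(w_max=1.0), 1, 10)
    ledger.record([0], 5)
    ledger.finalize_until(500)
    assert np.all(ledger.pending == 0.0)


def test_paired_cycle_pending_deltas():
    """One a-fires / b-fires-10ms-later cycle leaves the derived deltas."""
    net = NetworkSpec(max_delay_ms=1, w_min=0.0, w_max=0.25)
    pop = add_population(net, "pair", 2, "aeif", default_params("aeif"))
    connect_all_to_all(net, pop, pop, 0.1, 1, plastic=True)
    net.synapses.sort_by_pre()
    ledger = PlasticityLedger(net.synapses, FIG_CFG, 1, 2)
    ledger.record([0], 100)
    ledger.record([1], 110)
    ledger.finalize_until(400)
    ab = np.flatnonzero((net.synapses.pre == 0) & (net.synapses.post == 1))[0]
    ba = np.flatnonzero((net.synapses.pre == 1) & (net.synapses.post == 0))[0]
    assert np.isclose(ledger.pending[ab], 0.1 * np.exp(-0.5))    # ~ +0.06065
    assert np.isclose(ledger.pending[ba], -0.12 * np.exp(-0.5))  # ~ -0.07278


def test_arrival_time_pairing_shifts_dt_by_conduction_delay():
    """With arrival pairing, Δt is measured from pre arrival, not emission."""
    net = NetworkSpec(max_delay_ms=7, w_min=0.0, w_max=1.0)
    add_population(net, "p", 2, "lif", default_params("lif"))
    net.synapses.append([0], [1], [0.5], [7], [True])
    cfg = STDPConfig(w_max=1.0, pairing="arrival")
    ledger = PlasticityLedger(net.synapses, cfg, 7, 2)
    ledger.record([0], 100)      # arrives at post at t = 107
    ledger.record([1], 110)
    ledger.finalize_until(400)
    assert np.isclose(ledger.pending[0], 0.1 * np.exp(-3.0 / 20.0))


def test_deferred_equals_online_nearest_neighbor(small_plastic_net):
    """Batch-deferred pairing == per-synapse online pairing on random trains."""
    net, _ = small_plastic_net
    cfg = STDPConfig(A_plus=0.01, A_minus=0.012, w_max=1.0)
    ledger = PlasticityLedger(net.synapses, cfg, 1, 10)
    rng = np.random.default_rng(7)
    trains = poisson_trains(10, 10_000, rate_hz=20.0, rng=rng)
    _feed(ledger, trains)
    ledger.finalize_until(10_000)
    times = [[t for t, ids in enumerate(trains) if i in ids] for i in range(10)]
    syn = net.synapses
    expected = np.zeros(len(syn))
    W = cfg.window(1)
    for r in range(len(syn)):
        pairs = nearest_neighbor_pairs(times[syn.pre[r]], times[syn.post[r]],
                                       window_ms=W)
        expected[r] = sum(stdp_delta_w(dt, cfg) for dt, _ in pairs)
    assert np.allclose(ledger.pending, expected, rtol=1e-9, atol=1e-12)


def test_truncated_rule_close_to_untruncated(small_plastic_net):
    """The deferral-window cutoff discards < 1% of any pairing amplitude."""
    net, _ = small_plastic_net
    cfg = STDPConfig(A_plus=0.01, A_minus=0.012, w_max=1.0)
    ledger = PlasticityLedger(net.synapses, cfg, 1, 10)
    rng = np.random.default_rng(3)
    trains = poisson_trains(10, 5_000, rate_hz=5.0, rng=rng)
    _feed(ledger, trains)
    ledger.finalize_until(5_000)
    times = [[t for t, ids in enumerate(trains) if i in ids] for i in range(10)]
    syn = net.synapses
    for r in range(len(syn)):
        pairs = nearest_neighbor_pairs(times[syn.pre[r]], times[syn.post[r]])
        full = sum(stdp_delta_w(dt, cfg) for dt, _ in pairs)
        n_pairs = max(len(pairs), 1)
        assert abs(ledger.pending[r] - full) <= 0.007 * 0.012 * n_pairs


def test_commit_applies_bounds_and_counts(small_plastic_net):
    net, _ = small_plastic_net
    cfg = STDPConfig(w_min=0.0, w_max=0.25)
    net.synapses.weight[:] = 0.1
    ledger = PlasticityLedger(net.synapses, cfg, 1, 10)
    row = ledger.p_rows[0]
    ledger.pending[row] = 0.2
    assert ledger.commit(net.synapses.weight) == 1
    assert net.synapses.weight[row] == 0.25           # clipped at the bound
    assert np.all(ledger.pending == 0.0)
    assert ledger.commit(net.synapses.weight) == 0    # nothing pending
    # repeated depression saturates exactly at the lower bound and stays
    for _ in range(5):
        ledger.pending[row] = -0.07
        ledger.commit(net.synapses.weight)
    assert net.synapses.weight[row] == 0.0


def test_weights_stay_in_bounds_after_every_commit(small_plastic_net):
    net, _ = small_plastic_net
    cfg = STDPConfig(A_plus=0.3, A_minus=0.35, w_min=0.0, w_max=1.0)
    ledger = PlasticityLedger(net.synapses, cfg, 1, 10)
    rng = np.random.default_rng(11)
    trains = poisson_trains(10, 2_000, rate_hz=40.0, rng=rng)
    for t, ids in enumerate(trains):
        ledger.record(ids, t)
        if (t + 1) % 100 == 0:
            ledger.finalize_until(t - ledger.window)
            ledger.commit(net.synapses.weight)
            w = net.synapses.weight[ledger.p_rows]
            assert np.all((w >= cfg.w_min) & (w <= cfg.w_max))


def test_commit_frequency_invariance_without_bound_hits():
    """Commit cadence cannot matter when no weight ever reaches a bound."""
    results = []
    for interval in (1, 1000):
        net = NetworkSpec(max_delay_ms=1, w_min=0.0, w_max=1.0)
        pop = add_population(net, "p", 10, "lif", default_params("lif"))
        connect_all_to_all(net, pop, pop, 0.5, 1, plastic=True)
        net.synapses.sort_by_pre()
        cfg = STDPConfig(A_plus=1e-4, A_minus=1.2e-4, w_min=0.0, w_max=1.0,
                         commit_interval_ms=interval)
        ledger = PlasticityLedger(net.synapses, cfg, 1, 10)
        rng = np.random.default_rng(5)
        trains = poisson_trains(10, 3_000, rate_hz=20.0, rng=rng)
        for t, ids in enumerate(trains):
            ledger.record(ids, t)
            if (t + 1) % interval == 0:
                ledger.finalize_until(t - ledger.window)
                ledger.commit(net.synapses.weight)
        ledger.finalize_until(3_000)
        ledger.commit(net.synapses.weight)
        results.append(net.synapses.weight.copy())
    assert np.allclose(results[0], results[1], rtol=0, atol=1e-12)


def test_plasticity_disabled_leaves_weights_untouched():
    from spikesim.engine import Engine, SimulationConfig, StimulusSchedule
    from spikesim.experiments import build_polychronous_network
    net, stim, _ = build_polychronous_network(seed=2)
    before = None
    eng = Engine(net, SimulationConfig(duration_ms=500, seed=2), stim, stdp=None)
    before = net.synapses.weight.copy()
    eng.run()
    assert np.array_equal(net.synapses.weight, before)
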
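"""Network data model: populations, synapse tables, toroidal geometry.

A :class:`NetworkSpec` is the simulated graph: an ordered list of neuron
populations (whose global indices are the concatenation of the populations
in declaration order) plus a flat synapse table of
(pre, post, weight, integer delay, plastic) rows with global weight bounds
for plastic synapses.

Connectivity builders cover the preset experiments: fixed out-degree
fan-out, all-to-all, and distance-dependent Gaussian sampling on a 2-D
torus (minimum-image Euclidean metric).  All samplers are seeded and
deterministic; self-connections are excluded everywhere and targets are
drawn without replacement.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .neurons import MODEL_REGISTRY, model_param_names

SIGNS = ("exc", "inh")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a single run seed.

    Distinct names yield statistically independent streams, so e.g. the
    connectivity draw does not perturb the noise draw when one consumer
    changes.
    """
    key = zlib.crc32(name.encode())
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(key,))))


@dataclass
class PopulationSpec:
    """A homogeneous group of neurons sharing one model and parameter set."""

    pop_id: str
    size: int
    model_id: str
    params: dict
    sign: str = "exc"
    positions: np.ndarray | None = None   # (size, 2) integer grid coordinates
    start: int = 0                        # first global neuron index

    @property
    def stop(self) -> int:
        return self.start + self.size

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


class SynapseTable:
    """Struct-of-arrays synapse list: pre, post, weight, delay_ms, plastic."""

    def __init__(self, pre=(), post=(), weight=(), delay_ms=(), plastic=()):
        self.pre = np.asarray(pre, dtype=np.int64)
        self.post = np.asarray(post, dtype=np.int64)
        self.weight = np.asarray(weight, dtype=np.float64)
        self.delay_ms = np.asarray(delay_ms, dtype=np.int64)
        self.plastic = np.asarray(plastic, dtype=bool)

    def __len__(self) -> int:
        return self.pre.size

    def append(self, pre, post, weight, delay_ms, plastic):
        """Append a block of rows; returns the number of rows added."""
        pre = np.asarray(pre, dtype=np.int64)
        self.pre = np.concatenate([self.pre, pre])
        self.post = np.concatenate([self.post, np.asarray(post, dtype=np.int64)])
        self.weight = np.concatenate([self.weight, np.asarray(weight, dtype=np.float64)])
        self.delay_ms = np.concatenate([self.delay_ms, np.asarray(delay_ms, dtype=np.int64)])
        self.plastic = np.concatenate([self.plastic, np.broadcast_to(plastic, pre.shape).astype(bool)])
        return pre.size

    def sort_by_pre(self):
        """Stable sort rows by presynaptic index (the engine's CSR order)."""
        order = np.argsort(self.pre, kind="stable")
        for name in ("pre", "post", "weight", "delay_ms", "plastic"):
            setattr(self, name, getattr(self, name)[order])

    def out_degrees(self, n_neurons: int) -> np.ndarray:
        return np.bincount(self.pre, minlength=n_neurons)


@dataclass
class NetworkSpec:
    """Populations + synapse table + delay horizon and plastic weight bounds."""

    populations: list[PopulationSpec] = field(default_factory=list)
    synapses: SynapseTable = field(default_factory=SynapseTable)
    max_delay_ms: int = 20
    w_min: float = 0.0
    w_max: float = 1.0

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def population(self, pop_id: str) -> PopulationSpec:
        for p in self.populations:
            if p.pop_id == pop_id:
                return p
        raise KeyError(f"no population named {pop_id!r}")

    def neuron_signs(self) -> np.ndarray:
        """+1 for excitatory neurons, -1 for inhibitory, by global index."""
        out = np.empty(self.n_neurons, dtype=np.int8)
        for p in self.populations:
            out[p.start:p.stop] = 1 if p.sign == "exc" else -1
        return out

    def positions(self) -> np.ndarray:
        """Stacked (n_neurons, 2) grid coordinates; raises if any are missing."""
        parts = []
        for p in self.populations:
            if p.positions is None:
                raise ValueError(f"population {p.pop_id!r} has no positions")
            parts.append(np.asarray(p.positions, dtype=np.int64))
        return np.vstack(parts)


# ---------------------------------------------------------------------------
# Population / connection builders
# ---------------------------------------------------------------------------

def add_population(net: NetworkSpec, pop_id: str, size: int, model_id: str,
                   params: dict, sign: str = "exc",
                   positions=None) -> PopulationSpec:
    """Append a population; global indices are assigned contiguously."""
    if model_id not in MODEL_REGISTRY:
        raise KeyError(f"unknown neuron model {model_id!r}")
    if size < 1:
        raise ValueError("population size must be >= 1")
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}")
    expected = model_param_names(model_id)
    got = set(params)
    if got != expected:
        missing, extra = sorted(expected - got), sorted(got - expected)
        raise ValueError(
            f"params for model {model_id!r} mismatch: missing {missing}, extra {extra}")
    if positions is not None:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.shape != (size, 2):
            raise ValueError("positions must be one 2-D grid coordinate per neuron")
    pop = PopulationSpec(pop_id=pop_id, size=size, model_id=model_id,
                         params=dict(params), sign=sign, positions=positions,
                         start=net.n_neurons)
    net.populations.append(pop)
    return pop


def connect_fixed_fanout(net: NetworkSpec, pre_pop: PopulationSpec,
                         post_candidates: np.ndarray, fanout: int,
                         weight_sampler, delay_sampler, plastic: bool,
                         rng_seed: int) -> int:
    """Give every neuron of ``pre_pop`` exactly ``fanout`` outgoing synapses.

    Targets are drawn uniformly without replacement from ``post_candidates``
    (self-connections excluded); ``weight_sampler(rng, size)`` and
    ``delay_sampler(rng, size)`` supply per-synapse values.  Returns the row
    count added.
    """
    rng = substream(rng_seed, f"fanout:{pre_pop.pop_id}")
    post_candidates = np.asarray(post_candidates, dtype=np.int64)
    if fanout == 0:
        return 0
    pres, posts = [], []
    for i in pre_pop.indices:
        cand = post_candidates[post_candidates != i]
        if fanout > cand.size:
            raise ValueError(f"fanout {fanout} exceeds {cand.size} candidates for neuron {i}")
        targets = rng.choice(cand, size=fanout, replace=False)
        pres.append(np.full(fanout, i, dtype=np.int64))
        posts.append(targets)
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    weight = np.asarray(weight_sampler(rng, pre.size), dtype=np.float64)
    delay = np.rint(np.asarray(delay_sampler(rng, pre.size), dtype=np.float64)).astype(np.int64)
    delay = np.maximum(delay, 1)
    if np.any(delay > net.max_delay_ms):
        raise ValueError("delay sampler yielded a delay above max_delay_ms")
    return net.synapses.append(pre, post, weight, delay, plastic)


def connect_all_to_all(net: NetworkSpec, pre_pop: PopulationSpec,
                       post_pop: PopulationSpec, weight: float, delay: int,
                       plastic: bool = False) -> int:
    """One synapse per ordered (pre, post) pair, excluding self-connections."""
    pre_idx = pre_pop.indices
    post_idx = post_pop.indices
    pre = np.repeat(pre_idx, post_idx.size)
    post = np.tile(post_idx, pre_idx.size)
    keep = pre != post
    pre, post = pre[keep], post[keep]
    n = pre.size
    return net.synapses.append(pre, post, np.full(n, float(weight)),
                               np.full(n, int(delay)), plastic)


def toroidal_distance(p, q, dims) -> float:
    """Minimum-image Euclidean distance between grid points on a 2-D torus."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dims = np.asarray(dims, dtype=float)
    if np.any(p < 0) or np.any(p >= dims) or np.any(q < 0) or np.any(q >= dims):
        raise ValueError("coordinates must lie within the grid")
    d = np.abs(p - q)
    d = np.minimum(d, dims - d)
    return float(np.hypot(d[..., 0], d[..., 1])) if d.ndim > 1 else float(np.hypot(d[0], d[1]))


def grid_positions(dims) -> np.ndarray:
    """Row-major (x, y) coordinates for all cells of a (width, height) grid."""
    w, h = int(dims[0]), int(dims[1])
    idx = np.arange(w * h)
    return np.column_stack([idx % w, idx // w]).astype(np.int64)


def _displacement_grids(dims):
    """Distance from the origin cell to every cell, under wraparound."""
    w, h = int(dims[0]), int(dims[1])
    dx = np.minimum(np.arange(w), w - np.arange(w)).astype(float)
    dy = np.minimum(np.arange(h), h - np.arange(h)).astype(float)
    return np.hypot(dx[None, :], dy[:, None])  # shape (h, w), index [y, x]


def sample_gaussian_targets(source: int, positions: np.ndarray, dims,
                            sigma: float, n_syn: int,
                            rng: np.random.Generator,
                            candidates: np.ndarray | None = None):
    """Draw ``n_syn`` targets without replacement, P(target) ∝ exp(-d²/2σ²).

    d is the toroidal (minimum-image) distance from the source neuron.
    Sampling uses the Gumbel-top-k equivalence with successive
    draws-without-replacement.  Returns (targets, distances).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    w, h = int(dims[0]), int(dims[1])
    dist0 = _displacement_grids(dims)                       # origin-centred
    sx, sy = positions[source]
    # distance from the source to cell (x, y): roll the origin-centred grid
    dist = np.roll(np.roll(dist0, sy, axis=0), sx, axis=1)
    # map each candidate neuron to its cell distance
    if candidates is None:
        candidates = np.arange(positions.shape[0])
    cand = candidates[candidates != source]
    if n_syn > cand.size:
        raise ValueError(f"n_syn {n_syn} exceeds {cand.size} candidate targets")
    cx, cy = positions[cand, 0], positions[cand, 1]
    d = dist[cy % h, cx % w]
    logw = -0.5 * (d / sigma) ** 2
    keys = logw + rng.gumbel(size=cand.size)
    if n_syn < cand.size:
        top = np.argpartition(-keys, n_syn - 1)[:n_syn]
    else:
        top = np.arange(cand.size)
    return cand[top], d[top]


def connect_distance_gaussian(net: NetworkSpec, pre_pop: PopulationSpec,
                              sigma: float, n_syn: int, weight_sampler,
                              delay_rule, dims, rng_seed: int,
                              candidates: np.ndarray | None = None) -> int:
    """Distance-dependent Gaussian fan-out on the torus for every pre neuron.

    ``delay_rule(distances) -> integer delays`` sets per-synapse delays
    (e.g. proportional-to-distance with a cap); ``weight_sampler(rng, size)``
    sets weights.  Returns the row count added.
    """
    positions = net.positions()
    rng = substream(rng_seed, f"gaussian:{pre_pop.pop_id}")
    pres, posts, dists = [], [], []
    for i in pre_pop.indices:
        targets, d = sample_gaussian_targets(int(i), positions, dims, sigma,
                                             n_syn, rng, candidates)
        pres.append(np.full(targets.size, i, dtype=np.int64))
        posts.append(targets)
        dists.append(d)
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    d = np.concatenate(dists)
    weight = np.asarray(weight_sampler(rng, pre.size), dtype=np.float64)
    delay = np.asarray(delay_rule(d), dtype=np.int64)
    delay = np.clip(delay, 1, net.max_delay_ms)
    return net.synapses.append(pre, post, weight, delay, plastic=False)


def connect_distance_bernoulli(net: NetworkSpec, pre_pop: PopulationSpec,
                               sigma: float, n_syn_expected: float,
                               weight_sampler, delay_rule, dims,
                               rng_seed: int) -> int:
    """Per-pair Bernoulli variant of the Gaussian-distance connector.

    Each ordered pair (i, j) is connected independently with probability
    proportional to exp(-d²/2σ²), normalized so the *expected* out-degree is
    ``n_syn_expected`` (probabilities clipped at 1).  The fixed-fanout
    sampler :func:`connect_distance_gaussian` is the preset default; this
    form models the "varying number of postsynaptic targets" reading.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    positions = net.positions()
    w, h = int(dims[0]), int(dims[1])
    dist0 = _displacement_grids(dims)
    rng = substream(rng_seed, f"bernoulli:{pre_pop.pop_id}")
    all_idx = np.arange(positions.shape[0])
    pres, posts, dists = [], [], []
    for i in pre_pop.indices:
        sx, sy = positions[i]
        dist = np.roll(np.roll(dist0, sy, axis=0), sx, axis=1)
        cand = all_idx[all_idx != i]
        d = dist[positions[cand, 1] % h, positions[cand, 0] % w]
        wgt = np.exp(-0.5 * (d / sigma) ** 2)
        p = np.minimum(n_syn_expected * wgt / wgt.sum(), 1.0)
        keep = rng.random(cand.size) < p
        pres.append(np.full(int(keep.sum()), i, dtype=np.int64))
        posts.append(cand[keep])
        dists.append(d[keep])
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    d = np.concatenate(dists)
    weight = np.asarray(weight_sampler(rng, pre.size), dtype=np.float64)
    delay = np.clip(np.asarray(delay_rule(d), dtype=np.int64), 1, net.max_delay_ms)
    return net.synapses.append(pre, post, weight, delay, plastic=False)


def proportional_delay_rule(cap_ms: int, d_max: float):
    """Delay = clip(round(cap · d / d_max), 1, cap): proportional with a cap."""
    def rule(d):
        return np.clip(np.rint(cap_ms * np.asarray(d, dtype=float) / d_max), 1, cap_ms)
    return rule


def validate_network(net: NetworkSpec) -> list[str]:
    """Report (not raise) every invariant violation; empty list iff valid."""
    report: list[str] = []
    n = net.n_neurons
    start = 0
    for p in net.populations:
        if p.start != start:
            report.append(f"population {p.pop_id!r} indices not contiguous")
        start = p.stop
        if p.positions is not None and len(p.positions) != p.size:
            report.append(f"population {p.pop_id!r} positions length != size")
    syn = net.synapses
    if len(syn):
        if syn.pre.min() < 0 or syn.pre.max() >= n or syn.post.min() < 0 or syn.post.max() >= n:
            report.append("synapse index outside [0, total_neurons)")
        if np.any(syn.delay_ms < 1):
            report.append("delay below 1 ms")
        if np.any(syn.delay_ms > net.max_delay_ms):
            report.append(f"delay above max_delay_ms={net.max_delay_ms}")
        pl = syn.plastic
        if np.any(syn.weight[pl] < net.w_min) or np.any(syn.weight[pl] > net.w_max):
            report.append("plastic weight outside [w_min, w_max]")
        if np.any(syn.pre == syn.post):
            report.append("self-connection present")
    if net.max_delay_ms < 1:
        report.append("max_delay_ms below 1")
    return report


# ---------------------------------------------------------------------------
# Serialization: JSON header + TSV edge list
# ---------------------------------------------------------------------------

def save_network(net: NetworkSpec, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` (header) and ``<prefix>.tsv`` (edge list)."""
    prefix = Path(prefix)
    header = {
        "populations": [
            {
                "pop_id": p.pop_id, "size": p.size, "model_id": p.model_id,
                "params": {k: float(v) for k, v in p.params.items()},
                "sign": p.sign,
                "positions": None if p.positions is None else np.asarray(p.positions).tolist(),
            }
            for p in net.populations
        ],
        "max_delay_ms": int(net.max_delay_ms),
        "w_min": float(net.w_min),
        "w_max": float(net.w_max),
    }
    json_path = prefix.with_suffix(".json")
    tsv_path = prefix.with_suffix(".tsv")
    json_path.write_text(json.dumps(header, indent=1, sort_keys=True) + "\n")
    syn = net.synapses
    with open(tsv_path, "w") as fh:
        fh.write("pre\tpost\tweight\tdelay_ms\tplastic\n")
        for i in range(len(syn)):
            fh.write(f"{syn.pre[i]}\t{syn.post[i]}\t{float(syn.weight[i])!r}\t"
                     f"{syn.delay_ms[i]}\t{int(syn.plastic[i])}\n")
    return json_path, tsv_path


def load_network(prefix) -> NetworkSpec:
    """Inverse of :func:`save_network`."""
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    net = NetworkSpec(max_delay_ms=header["max_delay_ms"],
                      w_min=header["w_min"], w_max=header["w_max"])
    for p in header["populations"]:
        add_population(net, p["pop_id"], p["size"], p["model_id"], p["params"],
                       p["sign"],
                       None if p["positions"] is None else np.asarray(p["positions"]))
    data = np.genfromtxt(prefix.with_suffix(".tsv"), delimiter="\t",
                         skip_header=1, dtype=None, encoding=None)
    if data.size:
        data = np.atleast_1d(data)
        net.synapses = SynapseTable(
            pre=[r[0] for r in data], post=[r[1] for r in data],
            weight=[r[2] for r in data], delay_ms=[r[3] for r in data],
            plastic=[bool(r[4]) for r in data])
    return net
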
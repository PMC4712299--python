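"""Two-phase 1 ms simulation loop with stimulation, noise and recording.

Each step t first computes the synaptic drive delivered for this step (only
spikes emitted at steps <= t-1 can contribute, since the minimum delay is
1 ms), adds external stimulus and noise currents, and advances all neuron
states (phase one); spikes detected this step are then propagated into the
delay ring buffer and recorded into the plasticity ledger, with batch
weight commits at fixed intervals (phase two).

Runs are fully reproducible for a fixed seed: connectivity, noise and
stimulus each draw from named substreams of one run seed.  An engine can be
stepped in chunks (``run`` accumulates), and ``clone`` snapshots the
complete state — neuron arrays, ring buffer, filter state, plasticity
ledger and RNG streams — so a split run resumed from a snapshot matches an
unbroken one exactly.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSpec, substream, validate_network
from .neurons import MODEL_REGISTRY
from .stdp import PlasticityLedger, STDPConfig
from .synapses import (InputAccumulator, PSCFilterConfig, SpikeEventBuffer,
                       enqueue_spikes)


@dataclass
class RecordConfig:
    spikes: bool = True               # append (t, id) raster entries
    vm_ids: tuple = ()                # neuron ids whose Vm is traced each step
    weights_at_commits: bool = False  # snapshot plastic weights at each commit


@dataclass
class NoiseConfig:
    kind: str = "gaussian"            # "gaussian" | "uniform"
    mean: float = 0.0                 # gaussian
    sd: float = 1.0
    low: float = 0.0                  # uniform
    high: float = 1.0


@dataclass
class SimulationConfig:
    duration_ms: int = 1000
    seed: int = 0
    dt_ms: float = 1.0                # the engine grid is fixed at 1 ms
    filter: PSCFilterConfig = field(default_factory=PSCFilterConfig)
    record: RecordConfig = field(default_factory=RecordConfig)
    noise: NoiseConfig | None = None
    integrators: dict = field(default_factory=dict)  # model_id -> IntegratorConfig

    def validate(self, n_neurons: int):
        if self.duration_ms < 1:
            raise ValueError("duration_ms must be >= 1")
        if self.dt_ms != 1.0:
            raise ValueError("the engine step is fixed at 1 ms")
        for i in self.record.vm_ids:
            if not 0 <= i < n_neurons:
                raise ValueError(f"recorded neuron id {i} out of range")


class StimulusSchedule:
    """External current injection: deterministic pulses and/or random drive.

    ``entries`` is an iterable of (t_ms, neuron_id, amplitude) rows applied
    at exactly those steps.  ``random_neuron_amp`` additionally injects that
    amplitude into one uniformly chosen neuron every millisecond (the
    polychronous protocol's background drive).
    """

    def __init__(self, entries=(), random_neuron_amp: float | None = None):
        entries = sorted((int(t), int(i), float(a)) for t, i, a in entries)
        self.t = np.array([e[0] for e in entries], dtype=np.int64)
        self.ids = np.array([e[1] for e in entries], dtype=np.int64)
        self.amps = np.array([e[2] for e in entries])
        self.random_neuron_amp = random_neuron_amp

    @staticmethod
    def pulses(pulse_list):
        """Build from (t_start, duration_ms, neuron_id, amplitude) pulses."""
        entries = []
        for t0, dur, nid, amp in pulse_list:
            entries.extend((t0 + k, nid, amp) for k in range(int(dur)))
        return StimulusSchedule(entries)

    def validate(self, n_neurons: int, duration_ms: int | None = None):
        if self.ids.size and (self.ids.min() < 0 or self.ids.max() >= n_neurons):
            raise ValueError("stimulus neuron id out of range")
        if self.t.size and self.t.min() < 0:
            raise ValueError("stimulus times must be >= 0")


def make_noise_generator(kind: str, params: dict, seed: int, n: int):
    """Per-step per-neuron current source; reproducible under the seed."""
    rng = substream(seed, "noise")
    if kind == "gaussian":
        mean, sd = params.get("mean", 0.0), params.get("sd", 1.0)
        if sd < 0:
            raise ValueError("sd must be >= 0")
        return lambda: rng.normal(mean, sd, size=n)
    if kind == "uniform":
        low, high = params.get("low", 0.0), params.get("high", 1.0)
        return lambda: rng.uniform(low, high, size=n)
    raise ValueError(f"unknown noise kind {kind!r}")


@dataclass
class RunStats:
    spike_count: int = 0
    delivered_events: int = 0
    wall_time_s: float = 0.0
    commits: int = 0
    synapses_changed: int = 0


class RecordingSet:
    """Raster, Vm traces, weight snapshots, per-step counts and run stats."""

    def __init__(self, vm_ids=()):
        self._raster_t: list[np.ndarray] = []
        self._raster_i: list[np.ndarray] = []
        self.vm_ids = tuple(vm_ids)
        self._vm: list[np.ndarray] = []
        self._vm_t: list[int] = []
        self.weight_snapshots: list[tuple[int, np.ndarray]] = []
        self._counts: list[np.ndarray] = []
        self.stats = RunStats()

    @property
    def raster(self) -> np.ndarray:
        """(n_spikes, 2) array of (time_ms, neuron_id), time-sorted."""
        if not self._raster_t:
            return np.empty((0, 2), dtype=np.int64)
        return np.column_stack([np.concatenate(self._raster_t),
                                np.concatenate(self._raster_i)])

    @property
    def counts(self) -> np.ndarray:
        """Per-step population spike counts (always collected)."""
        if not self._counts:
            return np.empty(0, dtype=np.int32)
        return np.concatenate(self._counts)

    @property
    def vm(self) -> dict:
        """time array plus one trace per recorded neuron id."""
        if not self._vm:
            return {"time_ms": np.empty(0), **{i: np.empty(0) for i in self.vm_ids}}
        block = np.vstack(self._vm)
        out = {"time_ms": np.asarray(self._vm_t)}
        for k, i in enumerate(self.vm_ids):
            out[i] = block[:, k]
        return out


class Engine:
    """Stateful simulator; construct once, then ``run`` (repeatedly)."""

    def __init__(self, net: NetworkSpec, sim: SimulationConfig,
                 stim: StimulusSchedule | None = None,
                 stdp: STDPConfig | None = None):
        problems = validate_network(net)
        if problems:
            raise ValueError("invalid network: " + "; ".join(problems))
        sim.validate(net.n_neurons)
        if stim is not None:
            stim.validate(net.n_neurons)
        self.net = net
        self.sim = sim
        self.stim = stim
        self.n = net.n_neurons
        net.synapses.sort_by_pre()                     # canonical CSR order
        syn = net.synapses
        self.indptr = np.searchsorted(syn.pre, np.arange(self.n + 1))
        self.out_degree = self.indptr[1:] - self.indptr[:-1]
        self._lane = None
        if sim.filter.mode == "conductance":
            self._lane = (syn.weight < 0).astype(np.int64)  # 0 exc, 1 inh
        lanes = 2 if sim.filter.mode == "conductance" else 1
        self.buffer = SpikeEventBuffer(self.n, net.max_delay_ms, lanes=lanes)
        self.accumulator = InputAccumulator(self.n, sim.filter)
        self.blocks = self._build_blocks()
        self.ledger = None
        self.stdp = stdp
        if stdp is not None:
            stdp.validate()
            self.ledger = PlasticityLedger(syn, stdp, net.max_delay_ms, self.n)
        self.t = 0
        self._stim_ptr = 0
        self._stim_rng = substream(sim.seed, "stimulus")
        self._noise = None
        if sim.noise is not None:
            nz = sim.noise
            params = ({"mean": nz.mean, "sd": nz.sd} if nz.kind == "gaussian"
                      else {"low": nz.low, "high": nz.high})
            self._noise = make_noise_generator(nz.kind, params, sim.seed, self.n)
        self.recordings = RecordingSet(vm_ids=sim.record.vm_ids)
        self._vm_ids = np.asarray(sim.record.vm_ids, dtype=np.int64)
        self._count_buf: list = []
        # hot-loop caches (the synapse arrays are shared, not copied, so
        # plasticity commits are visible here)
        self._post = syn.post
        self._delay = syn.delay_ms
        self._conductance = sim.filter.mode == "conductance"

    # -- construction helpers ----------------------------------------------

    def _build_blocks(self):
        blocks = []
        pops = self.net.populations
        i = 0
        while i < len(pops):
            j = i
            while j < len(pops) and pops[j].model_id == pops[i].model_id:
                j += 1
            group = pops[i:j]
            model_id = group[0].model_id
            integ = self.sim.integrators.get(model_id)
            block = MODEL_REGISTRY[model_id].block_cls(group, integ)
            blocks.append((slice(group[0].start, group[j - i - 1].stop), block))
            i = j
        return blocks

    # -- state views --------------------------------------------------------

    @property
    def V(self) -> np.ndarray:
        out = np.empty(self.n)
        for sl, block in self.blocks:
            out[sl] = block.V
        return out

    def clone(self) -> "Engine":
        """Deep-copy snapshot (state arrays, buffers, ledger, RNG streams)."""
        return copy.deepcopy(self)

    # -- the loop -----------------------------------------------------------

    def _stimulus_current(self, I):
        stim = self.stim
        if stim is None:
            return
        t = self.t
        p = self._stim_ptr
        times = stim.t
        while p < times.size and times[p] == t:
            I[stim.ids[p]] += stim.amps[p]
            p += 1
        self._stim_ptr = p
        if stim.random_neuron_amp is not None:
            I[self._stim_rng.integers(0, self.n)] += stim.random_neuron_amp

    def step(self):
        """Advance one 1 ms step (both phases)."""
        t = self.t
        rec = self.recordings
        # ---- phase one: drive assembly and neuron state update
        V = self.V if self._conductance else None
        I = self.accumulator.accumulate(self.buffer, V)
        self._stimulus_current(I)
        if self._noise is not None:
            I += self._noise()
        if len(self.blocks) == 1:
            fired_ids = np.flatnonzero(self.blocks[0][1].step(I))
        else:
            parts = []
            for sl, block in self.blocks:
                parts.append(np.flatnonzero(block.step(I[sl])) + sl.start)
            fired_ids = np.concatenate(parts)
        nf = fired_ids.size
        # ---- recording
        self._count_buf.append(nf)
        if nf and self.sim.record.spikes:
            rec._raster_t.append(np.full(nf, t, dtype=np.int64))
            rec._raster_i.append(fired_ids)
        if self._vm_ids.size:
            rec._vm.append(self.V[self._vm_ids].copy())
            rec._vm_t.append(t)
        rec.stats.spike_count += int(nf)
        # ---- phase two: propagation and plasticity
        if nf:
            delivered = enqueue_spikes(self.buffer, fired_ids, self.indptr,
                                       self._post,
                                       self.net.synapses.weight,
                                       self._delay,
                                       lane=self._lane)
            rec.stats.delivered_events += delivered
            if self.ledger is not None:
                self.ledger.record(fired_ids, t)
        if self.ledger is not None and (t + 1) % self.stdp.commit_interval_ms == 0:
            self.ledger.finalize_until(t - self.ledger.window)
            changed = self.ledger.commit(self.net.synapses.weight)
            rec.stats.commits += 1
            rec.stats.synapses_changed += changed
            if self.sim.record.weights_at_commits:
                rec.weight_snapshots.append(
                    (t, self.net.synapses.weight[self.ledger.p_rows].copy()))
        self.buffer.advance()
        self.t = t + 1

    def run(self, duration_ms: int | None = None) -> RecordingSet:
        """Simulate ``duration_ms`` further steps (default: config duration)."""
        steps = int(duration_ms if duration_ms is not None else self.sim.duration_ms)
        t0 = time.perf_counter()
        for _ in range(steps):
            self.step()
        self.recordings.stats.wall_time_s += time.perf_counter() - t0
        self.recordings._counts.append(np.asarray(self._count_buf, dtype=np.int32))
        self._count_buf = []
        return self.recordings

    def flush_plasticity(self) -> int:
        """Finalize every recorded pairing and commit; exact at end of a run."""
        if self.ledger is None:
            return 0
        self.ledger.finalize_until(self.t)
        return self.ledger.commit(self.net.synapses.weight)


def run(net: NetworkSpec, sim: SimulationConfig,
        stim: StimulusSchedule | None = None,
        stdp: STDPConfig | None = None) -> RecordingSet:
    """One-shot convenience wrapper: build an engine and run it to completion."""
    eng = Engine(net, sim, stim, stdp)
    return eng.run()


def spike_delivery_rate(stats: RunStats) -> float:
    """Delivered synaptic events per wall-clock second (throughput metric)."""
    if stats.wall_time_s <= 0:
        raise ZeroDivisionError("run has no measured wall time")
    return stats.delivered_events / stats.wall_time_s
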
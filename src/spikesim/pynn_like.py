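"""A thin PyNN-flavoured programmatic session over the simulator.

Mirrors the familiar population/projection vocabulary — ``setup`` (timestep,
max_delay, seed, plus hardware tuning keys accepted as no-ops), population
declaration, all-to-all / fixed-probability connectors, current injection,
recording, ``run`` and ``get_data`` — and maps it directly onto the network
model and engine modules.  It is a convenience veneer, not a compliant PyNN
backend.
"""

from __future__ import annotations

import logging

import numpy as np

from .engine import Engine, RecordConfig, SimulationConfig, StimulusSchedule
from .network import NetworkSpec, add_population, connect_all_to_all, substream
from .neurons import default_params

log = logging.getLogger("spikesim")

_HW_KEYS = {"parallelism", "clock_frequency", "fpga_count", "num_fpgas"}


class Session:
    """One modelling session: build, run once, retrieve data."""

    def __init__(self):
        self._setup_done = False
        self._net: NetworkSpec | None = None
        self._engine: Engine | None = None
        self._record: dict = {}
        self._stim_entries: list = []
        self._seed = 0

    # -- PyNN-style vocabulary ---------------------------------------------

    def setup(self, timestep: float = 1.0, max_delay: int = 16, seed: int = 0,
              **hardware_kwargs):
        if timestep != 1.0:
            raise ValueError("the engine timestep is fixed at 1 ms")
        for key in sorted(hardware_kwargs):
            if key in _HW_KEYS:
                log.warning("setup key %r accepted with no effect", key)
            else:
                raise TypeError(f"unknown setup argument {key!r}")
        self._net = NetworkSpec(max_delay_ms=int(max_delay))
        self._setup_done = True
        self._seed = seed
        return self

    def _require_setup(self):
        if not self._setup_done:
            raise RuntimeError("call setup() before building the model")

    def Population(self, size: int, model_id: str, params: dict | None = None,
                   sign: str = "exc", label: str | None = None):
        self._require_setup()
        label = label or f"pop{len(self._net.populations)}"
        params = params if params is not None else default_params(model_id)
        return add_population(self._net, label, size, model_id, params, sign)

    def connect(self, pre, post, weight: float = 0.1, delay: int = 1,
                method: str = "all_to_all", p: float | None = None,
                plastic: bool = False):
        self._require_setup()
        if method == "all_to_all":
            return connect_all_to_all(self._net, pre, post, weight, delay, plastic)
        if method == "fixed_probability":
            if p is None or not 0 <= p <= 1:
                raise ValueError("fixed_probability connector needs p in [0, 1]")
            rng = substream(self._seed, f"connect:{pre.pop_id}->{post.pop_id}")
            pre_idx = np.repeat(pre.indices, post.size)
            post_idx = np.tile(post.indices, pre.size)
            keep = (pre_idx != post_idx) & (rng.random(pre_idx.size) < p)
            n = int(keep.sum())
            return self._net.synapses.append(pre_idx[keep], post_idx[keep],
                                             np.full(n, float(weight)),
                                             np.full(n, int(delay)), plastic)
        raise ValueError(f"unknown connector {method!r}")

    def inject_current(self, pop, amplitude: float, t_start: int = 0,
                       duration: int = 1):
        self._require_setup()
        for i in pop.indices:
            self._stim_entries.extend((t_start + k, int(i), amplitude)
                                      for k in range(duration))

    def record(self, pop, what: str = "spikes"):
        self._require_setup()
        if pop not in self._net.populations:
            raise ValueError("record() on a population not declared in this session")
        self._record.setdefault(what, []).append(pop)

    def run(self, duration_ms: int):
        self._require_setup()
        vm_ids: tuple = ()
        if "v" in self._record:
            vm_ids = tuple(int(i) for p in self._record["v"] for i in p.indices)
        sim = SimulationConfig(duration_ms=int(duration_ms), seed=self._seed,
                               record=RecordConfig(spikes=True, vm_ids=vm_ids))
        stim = StimulusSchedule(self._stim_entries) if self._stim_entries else None
        self._engine = Engine(self._net, sim, stim)
        return self._engine.run()

    def get_data(self, pop, what: str = "spikes"):
        if self._engine is None:
            raise RuntimeError("run() must be called before get_data()")
        rec = self._engine.recordings
        if what == "spikes":
            raster = rec.raster
            m = (raster[:, 1] >= pop.start) & (raster[:, 1] < pop.stop)
            return raster[m]
        if what == "v":
            vm = rec.vm
            return {i: vm[i] for i in pop.indices if i in vm}
        raise ValueError(f"unknown data kind {what!r}")
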
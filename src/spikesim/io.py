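"""Configuration files, rasters, traces and weight tables (all plain text).

File formats are deliberately diff-able: rasters and weight snapshots are
TSV with a header line, networks are a JSON header plus a TSV edge list
(:func:`spikesim.network.save_network`), and run configs are YAML or JSON.
All writers emit deterministic byte streams for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .engine import RecordConfig, SimulationConfig, StimulusSchedule
from .experiments import (PairedProtocolConfig, PolychronousConfig,
                          ToroidalConfig, build_paired_stdp_experiment,
                          build_polychronous_network, build_toroidal_network)
from .network import NetworkSpec, load_network
from .stdp import STDPConfig
from .synapses import PSCFilterConfig

log = logging.getLogger("spikesim")

#: Setup keys from the original hardware-backed API surface, accepted for
#: script compatibility but without semantic effect in the software engine.
HARDWARE_NOOP_KEYS = frozenset({
    "parallelism", "clock_frequency", "fpga_count", "num_fpgas",
    "weight_cache", "precision",
})

PRESETS = ("paired_stdp", "toroidal", "polychronous")


# ---------------------------------------------------------------------------
# Spike rasters and weight tables
# ---------------------------------------------------------------------------

def write_spike_raster(raster, path):
    """TSV ``time_ms<TAB>neuron_id`` with a header; raster must be sorted."""
    raster = np.asarray(raster, dtype=np.int64).reshape(-1, 2)
    if raster.shape[0] > 1 and np.any(np.diff(raster[:, 0]) < 0):
        raise ValueError("raster times must be non-decreasing")
    with open(path, "w") as fh:
        fh.write("time_ms\tneuron_id\n")
        for t, i in raster:
            fh.write(f"{t}\t{i}\n")
    return Path(path)


def read_spike_raster(path) -> np.ndarray:
    """Inverse of :func:`write_spike_raster`; validates ordering per line."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "time_ms\tneuron_id":
            raise ValueError(f"{path}: line 1: bad header {header.strip()!r}")
        prev_t = None
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                t, i = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if prev_t is not None and t < prev_t:
                raise ValueError(f"{path}: line {lineno}: time goes backwards")
            prev_t = t
            rows.append((t, i))
    return np.asarray(rows, dtype=np.int64).reshape(-1, 2)


def write_vm_traces(vm: dict, path):
    """TSV: time_ms column plus one column per recorded neuron."""
    ids = [k for k in vm if k != "time_ms"]
    with open(path, "w") as fh:
        fh.write("time_ms\t" + "\t".join(f"n{i}" for i in ids) + "\n")
        for row in zip(vm["time_ms"], *(vm[i] for i in ids)):
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")
    return Path(path)


def write_weight_snapshot(net: NetworkSpec, rows, path):
    """TSV (pre, post, weight) for the given synapse rows."""
    syn = net.synapses
    rows = np.asarray(rows, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("pre\tpost\tweight\n")
        for r in rows:
            fh.write(f"{syn.pre[r]}\t{syn.post[r]}\t{float(syn.weight[r])!r}\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunBundle:
    net: NetworkSpec
    sim: SimulationConfig
    stim: StimulusSchedule | None
    stdp: STDPConfig | None
    preset: str | None = None


def _reject_unknown(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    noop = unknown & HARDWARE_NOOP_KEYS
    for key in sorted(noop):
        log.warning("config key %r in %s is a hardware tuning knob; "
                    "accepted with no effect", key, where)
    unknown -= noop
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> RunBundle:
    """Load and validate a YAML/JSON run config into a runnable bundle.

    Exactly one network source is required: ``preset`` (a name from
    PRESETS), ``network.path`` (a serialized network prefix) or
    ``network.inline`` is not supported for synapse tables beyond presets —
    inline declarations go through the programmatic API instead.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    _reject_unknown(data, {"preset", "network", "simulation", "stdp", "stimulus"},
                    "top level")
    preset = data.get("preset")
    net_section = data.get("network")
    if (preset is None) == (net_section is None):
        raise ValueError("config must name exactly one of 'preset' or 'network'")

    sim_section = dict(data.get("simulation", {}))
    _reject_unknown(sim_section, {"duration_ms", "seed", "filter", "record"},
                    "simulation")
    filt_section = dict(sim_section.get("filter", {}))
    _reject_unknown(filt_section, {"kind", "tau_ms", "mode"}, "simulation.filter")
    rec_section = dict(sim_section.get("record", {}))
    _reject_unknown(rec_section, {"spikes", "vm_ids", "weights_at_commits"},
                    "simulation.record")
    sim = SimulationConfig(
        duration_ms=int(sim_section.get("duration_ms", 1000)),
        seed=int(sim_section.get("seed", 0)),
        filter=PSCFilterConfig(kind=filt_section.get("kind", "delta"),
                               tau_ms=float(filt_section.get("tau_ms", 5.0)),
                               mode=filt_section.get("mode", "current")),
        record=RecordConfig(spikes=bool(rec_section.get("spikes", True)),
                            vm_ids=tuple(rec_section.get("vm_ids", ())),
                            weights_at_commits=bool(rec_section.get(
                                "weights_at_commits", False))))

    stdp_cfg = None
    if "stdp" in data and data["stdp"] is not None:
        s = dict(data["stdp"])
        _reject_unknown(s, {"A_plus", "A_minus", "tau_plus_ms", "tau_minus_ms",
                            "w_min", "w_max", "commit_interval_ms",
                            "deferral_window_ms", "pairing", "commit_drift",
                            "delta_carry"}, "stdp")
        stdp_cfg = STDPConfig(**s)
        stdp_cfg.validate()

    stim = None
    if "stimulus" in data and data["stimulus"] is not None:
        s = dict(data["stimulus"])
        _reject_unknown(s, {"entries", "random_neuron_amp"}, "stimulus")
        stim = StimulusSchedule(entries=s.get("entries", ()),
                                random_neuron_amp=s.get("random_neuron_amp"))

    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r} (expected one of {PRESETS})")
        net, preset_stim, preset_stdp = _build_preset(preset, sim.seed)
        stim = stim if stim is not None else preset_stim
        stdp_cfg = stdp_cfg if stdp_cfg is not None else preset_stdp
    else:
        _reject_unknown(dict(net_section), {"path"}, "network")
        net_path = Path(net_section["path"])
        if not net_path.with_suffix(".json").exists():
            raise FileNotFoundError(f"network file {net_path}.json does not exist")
        net = load_network(net_path)
    return RunBundle(net=net, sim=sim, stim=stim, stdp=stdp_cfg, preset=preset)


def _build_preset(preset: str, seed: int):
    if preset == "paired_stdp":
        return build_paired_stdp_experiment(PairedProtocolConfig())
    if preset == "toroidal":
        return build_toroidal_network(ToroidalConfig(), seed=seed), None, None
    return build_polychronous_network(PolychronousConfig(), seed=seed)


def dump_config(bundle: RunBundle) -> dict:
    """Serializable view of a bundle (presets round-trip by name)."""
    out: dict = {
        "simulation": {
            "duration_ms": bundle.sim.duration_ms,
            "seed": bundle.sim.seed,
            "filter": {"kind": bundle.sim.filter.kind,
                       "tau_ms": bundle.sim.filter.tau_ms,
                       "mode": bundle.sim.filter.mode},
            "record": {"spikes": bool(bundle.sim.record.spikes),
                       "vm_ids": list(bundle.sim.record.vm_ids),
                       "weights_at_commits": bundle.sim.record.weights_at_commits},
        },
    }
    if bundle.preset:
        out["preset"] = bundle.preset
    if bundle.stdp is not None and not bundle.preset:
        s = bundle.stdp
        out["stdp"] = {"A_plus": s.A_plus, "A_minus": s.A_minus,
                       "tau_plus_ms": s.tau_plus_ms, "tau_minus_ms": s.tau_minus_ms,
                       "w_min": s.w_min, "w_max": s.w_max,
                       "commit_interval_ms": s.commit_interval_ms}
    return out
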
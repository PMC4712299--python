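"""Preset experiments: paired-pulse STDP, toroidal network, polychronization.

Three reproducible study presets exercise the full stack:

* **Paired stimulation** — two mutually connected aEIF neurons are forced
  to fire 10 ms apart once per 250 ms cycle; under the additive
  nearest-neighbor rule the causally ordered synapse potentiates to the
  upper bound (0.25) while the reverse synapse depresses to 0.
* **Toroidal network** — neurons laid out on a 2-D torus with
  distance-dependent Gaussian connectivity (σ = 16 for inhibitory sources),
  delays proportional to distance capped at 16 ms for excitatory synapses
  and fixed at 1 ms for inhibitory ones, and uniform (0, 0.5) weights
  normalized by the fan-out n_syn.
* **Polychronous network** — 1000 Izhikevich neurons (800 regular-spiking
  excitatory, 200 fast-spiking inhibitory), fan-out 100, random 1-20 ms
  excitatory delays, STDP on excitatory synapses, and one randomly chosen
  neuron driven with amplitude 20 every millisecond.  With training the
  population rhythm shifts from the initial 2-4 Hz band to a 30-100 Hz
  gamma band, and time-locked polychronous groups can be triggered from
  anchor neurons after learning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import periodogram, welch

from .engine import (Engine, RecordConfig, RecordingSet, SimulationConfig,
                     StimulusSchedule)
from .network import (NetworkSpec, add_population, connect_all_to_all,
                      connect_fixed_fanout, connect_distance_gaussian,
                      grid_positions, proportional_delay_rule, substream)
from .neurons import default_params
from .stdp import STDPConfig
from .synapses import PSCFilterConfig


# ---------------------------------------------------------------------------
# Paired-stimulation STDP
# ---------------------------------------------------------------------------

@dataclass
class PairedProtocolConfig:
    """Alternate suprathreshold stimulation of two mutually coupled neurons.

    One cycle lasts ``period_ms``; neuron a's pulse starts the cycle and
    neuron b's follows ``offset_ms`` later, so each cycle contributes one
    pre-before-post pairing at +offset on a->b and one post-before-pre
    pairing at -offset on b->a.
    """

    pulse_amplitude: float = 2000.0   # pA, native aEIF input units
    pulse_width_ms: int = 5           # pulse length; period is period_ms
    period_ms: int = 250
    offset_ms: int = 10
    cycles: int = 6
    initial_weight: float = 0.1
    w_min: float = 0.0
    w_max: float = 0.25
    stdp: STDPConfig = field(default_factory=lambda: STDPConfig(
        A_plus=0.1, A_minus=0.12, tau_plus_ms=20.0, tau_minus_ms=20.0,
        w_min=0.0, w_max=0.25, commit_interval_ms=100))

    def validate(self):
        if not self.offset_ms < self.period_ms:
            raise ValueError("offset_ms must be smaller than the cycle period")
        if not self.w_min < self.w_max:
            raise ValueError("weight bounds must be ordered")


def build_paired_stdp_experiment(cfg: PairedProtocolConfig | None = None,
                                 ) -> tuple[NetworkSpec, StimulusSchedule, STDPConfig]:
    """Two aEIF neurons, mutual plastic synapses, alternating forced pulses."""
    cfg = cfg or PairedProtocolConfig()
    cfg.validate()
    net = NetworkSpec(max_delay_ms=1, w_min=cfg.w_min, w_max=cfg.w_max)
    pop = add_population(net, "pair", 2, "aeif", default_params("aeif"))
    connect_all_to_all(net, pop, pop, weight=cfg.initial_weight, delay=1,
                       plastic=True)
    pulses = []
    for k in range(cfg.cycles):
        pulses.append((k * cfg.period_ms, cfg.pulse_width_ms, 0, cfg.pulse_amplitude))
        pulses.append((k * cfg.period_ms + cfg.offset_ms, cfg.pulse_width_ms, 1,
                       cfg.pulse_amplitude))
    stim = StimulusSchedule.pulses(pulses)
    stdp = cfg.stdp
    stdp.w_min, stdp.w_max = cfg.w_min, cfg.w_max
    return net, stim, stdp


def run_paired_protocol(built=None, cycles: int | None = None, seed: int = 0,
                        cfg: PairedProtocolConfig | None = None):
    """Run the paired protocol; returns (recordings, trajectory dict).

    The trajectory holds the committed weight time series ``w_ab`` (row
    pre=0 -> post=1) and ``w_ba`` plus the commit times, including a final
    end-of-run flush commit.  A dry run of the first cycle checks that the
    pulse actually forces both neurons to spike.
    """
    cfg = cfg or PairedProtocolConfig()
    if cycles is not None:
        cfg.cycles = cycles
    net, stim, stdp = built if built is not None else build_paired_stdp_experiment(cfg)
    duration = cfg.cycles * cfg.period_ms + 2 * stdp.window(net.max_delay_ms)
    sim = SimulationConfig(duration_ms=max(duration, stdp.commit_interval_ms),
                           seed=seed,
                           record=RecordConfig(spikes=True, weights_at_commits=True))
    if cfg.cycles > 0:
        _dry_run_check(cfg, seed)
    eng = Engine(net, sim, stim, stdp)
    rec = eng.run()
    eng.flush_plasticity()
    syn = net.synapses
    ab = int(np.flatnonzero((syn.pre == 0) & (syn.post == 1))[0])
    ba = int(np.flatnonzero((syn.pre == 1) & (syn.post == 0))[0])
    rows = eng.ledger.p_rows.tolist()
    snaps = rec.weight_snapshots + [(eng.t, syn.weight[eng.ledger.p_rows].copy())]
    traj = {
        "t_ms": np.array([t for t, _ in snaps]),
        "w_ab": np.array([w[rows.index(ab)] for _, w in snaps]),
        "w_ba": np.array([w[rows.index(ba)] for _, w in snaps]),
    }
    return rec, traj


def _dry_run_check(cfg: PairedProtocolConfig, seed: int):
    """One-cycle probe: the pulse must be suprathreshold for both neurons."""
    probe = PairedProtocolConfig(pulse_amplitude=cfg.pulse_amplitude,
                                 pulse_width_ms=cfg.pulse_width_ms,
                                 period_ms=cfg.period_ms,
                                 offset_ms=cfg.offset_ms, cycles=1,
                                 initial_weight=cfg.initial_weight,
                                 w_min=cfg.w_min, w_max=cfg.w_max)
    net, stim, _ = build_paired_stdp_experiment(probe)
    sim = SimulationConfig(duration_ms=probe.period_ms, seed=seed)
    rec = Engine(net, sim, stim).run()
    raster = rec.raster
    if not (np.any(raster[:, 1] == 0) and np.any(raster[:, 1] == 1)):
        raise ValueError("stimulation pulse too weak to force spiking")


# ---------------------------------------------------------------------------
# Toroidal network
# ---------------------------------------------------------------------------

@dataclass
class ToroidalConfig:
    dims: tuple = (96, 96)            # grid; one neuron per cell
    n_syn: int = 1000                 # per-neuron fan-out
    sigma_exc: float = 32.0           # Gaussian S.D. for excitatory sources
    sigma_inh: float = 16.0           # and for inhibitory sources
    delay_cap_exc_ms: int = 16
    delay_inh_ms: int = 1
    weight_low: float = 0.0
    weight_high: float = 0.5
    weight_scale_by_nsyn: bool = True  # divide weights by n_syn/1000
    inh_fraction: float = 0.2
    model_id: str = "izhikevich"

    def validate(self):
        if self.sigma_exc <= 0 or self.sigma_inh <= 0:
            raise ValueError("sigma must be > 0")
        if self.delay_cap_exc_ms < 1 or self.delay_inh_ms < 1:
            raise ValueError("delay caps must be >= 1 ms")


def build_toroidal_network(cfg: ToroidalConfig | None = None, seed: int = 0) -> NetworkSpec:
    """Torus-structured network with distance-dependent Gaussian fan-out.

    Excitatory delays grow in proportion to toroidal distance, scaled so the
    farthest possible pair maps to the 16 ms cap; inhibitory delays are all
    1 ms (fast local inhibition).  Weights are uniform in (low, high),
    divided by n_syn/1000 when scaling is on so total expected drive stays
    comparable across fan-out scenarios.
    """
    cfg = cfg or ToroidalConfig()
    cfg.validate()
    w, h = cfg.dims
    n = w * h
    n_inh = int(round(cfg.inh_fraction * n))
    n_exc = n - n_inh
    pos = grid_positions(cfg.dims)
    # deterministic interleave: every k-th cell inhibitory (k = 1/inh_fraction)
    rng = substream(seed, "toroidal:signs")
    inh_mask = np.zeros(n, dtype=bool)
    inh_mask[rng.choice(n, size=n_inh, replace=False)] = True
    exc_idx = np.flatnonzero(~inh_mask)
    inh_idx = np.flatnonzero(inh_mask)
    net = NetworkSpec(max_delay_ms=max(cfg.delay_cap_exc_ms, cfg.delay_inh_ms),
                      w_min=0.0, w_max=cfg.weight_high)
    params = default_params(cfg.model_id)
    inh_params = dict(params)
    if cfg.model_id == "izhikevich":
        inh_params.update(a=0.1, d=2.0)
    # population order must keep global indices == grid cells: exc then inh
    # would break row-major layout, so use one population per sign with
    # explicit positions instead.
    exc = add_population(net, "exc", n_exc, cfg.model_id, params, "exc",
                         positions=pos[exc_idx])
    inh = add_population(net, "inh", n_inh, cfg.model_id, inh_params, "inh",
                         positions=pos[inh_idx])
    scale = (cfg.n_syn / 1000.0) if cfg.weight_scale_by_nsyn else 1.0

    def weights_exc(r, size):
        return r.uniform(cfg.weight_low, cfg.weight_high, size) / scale

    def weights_inh(r, size):
        return -r.uniform(cfg.weight_low, cfg.weight_high, size) / scale

    d_max = float(np.hypot(w / 2.0, h / 2.0))
    exc_rule = proportional_delay_rule(cfg.delay_cap_exc_ms, d_max)
    inh_rule = lambda d: np.full(np.asarray(d).shape, cfg.delay_inh_ms, dtype=np.int64)
    connect_distance_gaussian(net, exc, cfg.sigma_exc, cfg.n_syn, weights_exc,
                              exc_rule, cfg.dims, seed)
    connect_distance_gaussian(net, inh, cfg.sigma_inh, cfg.n_syn, weights_inh,
                              inh_rule, cfg.dims, seed)
    return net


# ---------------------------------------------------------------------------
# Polychronous network
# ---------------------------------------------------------------------------

@dataclass
class PolychronousConfig:
    n_neurons: int = 1000
    exc_fraction: float = 0.8
    fanout: int = 100
    delay_range_ms: tuple = (1, 20)
    inh_delay_fixed_1ms: bool = True   # inhibitory delay pinned at 1 ms
    input_amplitude: float = 20.0      # one random neuron per ms
    w_exc_init: float = 6.0
    w_inh_init: float = -5.0
    w_max: float = 10.0
    #: the reference polychronization protocol's plasticity conventions:
    #: arrival-time pairing (the afferents whose spikes *arrive* just before
    #: the target fires potentiate, selecting delay-matched groups), a
    #: +0.01/s drift on plastic weights, and 0.9-damped carryover of each
    #: second's summed delta into later commits
    stdp: STDPConfig = field(default_factory=lambda: STDPConfig(
        A_plus=0.1, A_minus=0.12, tau_plus_ms=20.0, tau_minus_ms=20.0,
        w_min=0.0, w_max=10.0, commit_interval_ms=1000, pairing="arrival",
        commit_drift=0.01, delta_carry=0.9))

    @property
    def connection_probability(self) -> float:
        return self.fanout / (self.n_neurons - 1)


def build_polychronous_network(cfg: PolychronousConfig | None = None, seed: int = 0,
                               ) -> tuple[NetworkSpec, StimulusSchedule, STDPConfig]:
    """1000 Izhikevich neurons, fan-out 100, heterogeneous delays, STDP.

    Excitatory neurons are regular-spiking and project to any other neuron
    with plastic synapses and uniform integer delays over the configured
    range; inhibitory neurons are fast-spiking, project to excitatory
    neurons only, with fixed -5 non-plastic weights and (by default) 1 ms
    delays.
    """
    cfg = cfg or PolychronousConfig()
    n = cfg.n_neurons
    n_exc = int(round(cfg.exc_fraction * n))
    n_inh = n - n_exc
    lo, hi = cfg.delay_range_ms
    net = NetworkSpec(max_delay_ms=int(hi), w_min=0.0, w_max=cfg.w_max)
    exc = add_population(net, "exc", n_exc, "izhikevich",
                         default_params("izhikevich"), "exc")
    inh = add_population(net, "inh", n_inh, "izhikevich",
                         default_params("izhikevich", a=0.1, d=2.0), "inh")
    connect_fixed_fanout(
        net, exc, np.arange(n), cfg.fanout,
        weight_sampler=lambda r, s: np.full(s, cfg.w_exc_init),
        delay_sampler=lambda r, s: r.integers(lo, hi + 1, size=s),
        plastic=True, rng_seed=seed)
    inh_delay = ((lambda r, s: np.ones(s)) if cfg.inh_delay_fixed_1ms
                 else (lambda r, s: r.integers(lo, hi + 1, size=s)))
    connect_fixed_fanout(
        net, inh, exc.indices, cfg.fanout,
        weight_sampler=lambda r, s: np.full(s, cfg.w_inh_init),
        delay_sampler=inh_delay, plastic=False, rng_seed=seed)
    stim = StimulusSchedule(random_neuron_amp=cfg.input_amplitude)
    return net, stim, cfg.stdp


def make_polychronous_engine(cfg: PolychronousConfig | None = None, seed: int = 0,
                             record_spikes: bool = False,
                             stdp_enabled: bool = True) -> Engine:
    """Engine wired for the polychronous preset (delta filter, 1 ms grid)."""
    net, stim, stdp = build_polychronous_network(cfg, seed)
    sim = SimulationConfig(duration_ms=1000, seed=seed,
                           filter=PSCFilterConfig(kind="delta"),
                           record=RecordConfig(spikes=record_spikes))
    return Engine(net, sim, stim, stdp if stdp_enabled else None)


# ---------------------------------------------------------------------------
# Rhythm analysis
# ---------------------------------------------------------------------------

@dataclass
class RhythmSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray
    dominant_frequency_hz: float
    band_hz: tuple


def rate_series(raster: np.ndarray, n_steps: int, t0: int = 0) -> np.ndarray:
    """1 ms-binned population firing-rate series from a (t, id) raster."""
    raster = np.asarray(raster)
    if raster.size == 0:
        return np.zeros(n_steps)
    t = raster[:, 0] - t0
    keep = (t >= 0) & (t < n_steps)
    return np.bincount(t[keep].astype(np.int64), minlength=n_steps).astype(float)


def rhythm_spectrum_from_rate(rate: np.ndarray, band_hz=(1.0, 150.0),
                              fs_hz: float = 1000.0, method: str = "welch",
                              peak: str = "above_background",
                              segment_ms: int = 1000) -> RhythmSpectrum:
    """Dominant rhythm of a mean-removed population-rate series.

    The spectrum is estimated either by Welch averaging over ``segment_ms``
    segments (default; tames single-periodogram variance) or by a raw
    periodogram.  The dominant frequency is, by default, the strongest
    *narrowband peak above the aperiodic background* — the power divided by
    a running-median estimate of the local background — which identifies the
    network oscillation even when broadband slow-envelope power is large;
    ``peak="max"`` selects the raw power argmax instead.
    """
    rate = np.asarray(rate, dtype=float)
    if rate.size < 2:
        raise ValueError("rate series too short")
    x = rate - rate.mean()
    if method == "welch":
        f, p = welch(x, fs=fs_hz, nperseg=min(int(segment_ms), x.size))
    elif method == "periodogram":
        f, p = periodogram(x, fs=fs_hz)
    else:
        raise ValueError(f"unknown spectrum method {method!r}")
    lo, hi = band_hz
    m = (f >= lo) & (f <= hi)
    if not np.any(m):
        raise ValueError("band contains no frequency bins")
    fb, pb = f[m], p[m]
    if peak == "above_background":
        bg = median_filter(pb, size=min(21, pb.size), mode="nearest")
        score = pb / np.maximum(bg, np.finfo(float).tiny)
    elif peak == "max":
        score = pb
    else:
        raise ValueError(f"unknown peak criterion {peak!r}")
    return RhythmSpectrum(freqs_hz=fb, power=pb,
                          dominant_frequency_hz=float(fb[np.argmax(score)]),
                          band_hz=(lo, hi))


def population_rhythm_spectrum(raster: np.ndarray, window_ms: int = 10_000,
                               band_hz=(1.0, 150.0), t0: int = 0,
                               **kwargs) -> RhythmSpectrum:
    """Rhythm spectrum of a spike raster over a window starting at ``t0``."""
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    if window_ms < 1000:
        raise ValueError("window must be at least 1 s")
    return rhythm_spectrum_from_rate(rate_series(raster, window_ms, t0),
                                     band_hz, **kwargs)


# ---------------------------------------------------------------------------
# Polychronous group detection
# ---------------------------------------------------------------------------

@dataclass
class PolychronousGroup:
    anchors: list                  # (neuron_id, relative firing time) pairs
    sequence: list                 # time-locked (neuron_id, t_ms) firings
    size: int


@dataclass
class GroupSearchConfig:
    anchor_count: int = 3
    min_group_size: int = 7
    strong_fraction: float = 0.95   # afferent counts as strong at >= frac*w_max
    probe_window_ms: int = 150
    trigger_amplitude: float = 300.0
    max_targets: int | None = None
    combinations_per_target: int = 1  # 1 = strongest anchors only


def trigger_and_record(net: NetworkSpec, anchor_ids, anchor_times,
                       duration_ms: int, amplitude: float = 300.0,
                       pulse_width_ms: int = 2, seed: int = 0) -> RecordingSet:
    """Stimulate anchors at given times in an otherwise quiet network."""
    pulses = [(int(t), pulse_width_ms, int(i), amplitude)
              for i, t in zip(anchor_ids, anchor_times)]
    stim = StimulusSchedule.pulses(pulses)
    sim = SimulationConfig(duration_ms=duration_ms, seed=seed)
    return Engine(net, sim, stim, stdp=None).run()


def find_polychronous_groups(net: NetworkSpec, cfg: GroupSearchConfig | None = None,
                             seed: int = 0) -> list[PolychronousGroup]:
    """Anchor-triggered search for time-locked firing sequences.

    For each excitatory target, its strongest plastic afferents (weight at
    least ``strong_fraction``·w_max) are candidate anchors; anchors are
    stimulated with relative timings that make their spikes arrive at the
    target simultaneously (offsets = max delay - own delay), the network is
    simulated for a short quiet window with noise and plasticity off, and
    the triggered sequence is kept as a group if it recruits at least
    ``min_group_size`` distinct neurons.
    """
    cfg = cfg or GroupSearchConfig()
    syn = net.synapses
    strong = syn.plastic & (syn.weight >= cfg.strong_fraction * net.w_max)
    groups: list[PolychronousGroup] = []
    targets = np.unique(syn.post[strong])
    if cfg.max_targets is not None:
        targets = targets[:cfg.max_targets]
    for tgt in targets:
        rows = np.flatnonzero(strong & (syn.post == tgt))
        if rows.size < cfg.anchor_count:
            continue
        rows = rows[np.argsort(-syn.weight[rows], kind="stable")]
        combos = itertools.combinations(rows, cfg.anchor_count)
        for combo in itertools.islice(combos, cfg.combinations_per_target):
            combo = np.asarray(combo)
            pre = syn.pre[combo]
            delays = syn.delay_ms[combo]
            rel = delays.max() - delays        # fire earlier if delay longer
            rec = trigger_and_record(net, pre, rel, cfg.probe_window_ms,
                                     cfg.trigger_amplitude, seed=seed)
            raster = rec.raster
            n_distinct = np.unique(raster[:, 1]).size if raster.size else 0
            if n_distinct >= cfg.min_group_size:
                groups.append(PolychronousGroup(
                    anchors=[(int(i), int(t)) for i, t in zip(pre, rel)],
                    sequence=[(int(i), int(t)) for t, i in raster],
                    size=int(n_distinct)))
    return groups
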
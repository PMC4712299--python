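"""Nearest-neighbor, presynaptic-centric, additive STDP with deferred commits.

The learning rule is pair-based and additive with exponential windows:

    Δw = +A_plus  · exp(-Δt / tau_plus)     for Δt > 0   (potentiation)
    Δw = -A_minus · exp(-|Δt| / tau_minus)  for Δt < 0   (depression)

with Δt = t_post - t_pre, so a presynaptic spike preceding its postsynaptic
partner potentiates.  Pairing is nearest-neighbor and presynaptic-centric:
each presynaptic spike interacts only with the latest postsynaptic spike at
or before it (depression) and the earliest one strictly after it
(potentiation); a postsynaptic spike may take part in several pairings.

Pairings are truncated at a deferral window W (default
max_delay + 5·max(tau_plus, tau_minus), where the discarded exponential
tail is below ~0.7% of the amplitude).  The window also licenses the
deferred batch scheme: once a presynaptic spike is older than W, no future
spike can change its pairings, so its weight deltas can be finalized and
held in a pending table until the next batch commit, at which point the
additive updates are applied and clipped to [w_min, w_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synapses import concat_ranges

# spike-time keys are packed as (neuron << TIME_BITS) | time for sorted search
_TIME_BITS = 32


@dataclass
class STDPConfig:
    A_plus: float = 0.1           # potentiation amplitude
    A_minus: float = 0.12         # depression amplitude (magnitude)
    tau_plus_ms: float = 20.0
    tau_minus_ms: float = 20.0
    w_min: float = 0.0
    w_max: float = 0.25
    commit_interval_ms: int = 100   # batch commit period
    deferral_window_ms: int | None = None  # default: max_delay + 5*max(tau)
    #: which presynaptic time enters Δt: "emission" pairs the somatic spike
    #: time; "arrival" adds the conduction delay first (the convention of the
    #: polychronization literature, where delay-matched afferents potentiate)
    pairing: str = "emission"
    #: constant added to every plastic weight at each commit (the reference
    #: polychronization protocol uses +0.01 per second); 0 disables
    commit_drift: float = 0.0
    #: fraction of each commit's summed delta carried over (damped) into the
    #: next commit, as in the reference protocol's derivative update (0.9
    #: there); 0 disables and recovers the memoryless additive commit
    delta_carry: float = 0.0

    def validate(self):
        if self.tau_plus_ms <= 0 or self.tau_minus_ms <= 0:
            raise ValueError("STDP time constants must be > 0")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.commit_interval_ms < 1:
            raise ValueError("commit_interval_ms must be >= 1")
        if self.pairing not in ("emission", "arrival"):
            raise ValueError(f"unknown pairing timing {self.pairing!r}")
        if not 0.0 <= self.delta_carry < 1.0:
            raise ValueError("delta_carry must lie in [0, 1)")

    def window(self, max_delay_ms: int) -> int:
        if self.deferral_window_ms is not None:
            return int(self.deferral_window_ms)
        return int(max_delay_ms + np.ceil(5.0 * max(self.tau_plus_ms, self.tau_minus_ms)))


def stdp_delta_w(dt, cfg: STDPConfig, window_ms: float | None = None):
    """Weight change for a single pairing with Δt = t_post - t_pre (ms).

    Δt = 0 yields 0; an optional window truncates pairings with |Δt| beyond
    it to 0.  Broadcasts over arrays.
    """
    dt = np.asarray(dt, dtype=float)
    mag = np.abs(dt)
    pot = cfg.A_plus * np.exp(-mag / cfg.tau_plus_ms)
    dep = -cfg.A_minus * np.exp(-mag / cfg.tau_minus_ms)
    out = np.where(dt > 0, pot, np.where(dt < 0, dep, 0.0))
    if window_ms is not None:
        out = np.where(np.abs(dt) <= window_ms, out, 0.0)
    return out if out.ndim else float(out)


def make_delta_w_table(cfg: STDPConfig, window_ms: int) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed Δw per integer Δt: (potentiation[1..W], depression[1..W]).

    An optional lookup-table optimization; the analytic formula is the
    source of truth and tests compare the two.
    """
    dts = np.arange(1, window_ms + 1, dtype=float)
    return (np.asarray(stdp_delta_w(dts, cfg)),
            np.asarray(stdp_delta_w(-dts, cfg)))


def nearest_neighbor_pairs(pre_times, post_times, window_ms: float | None = None):
    """Presynaptic-centric nearest-neighbor pairings of two spike trains.

    For each presynaptic spike t_pre emits up to two (dt, kind) tuples:
    ("depression", dt <= 0) with the latest postsynaptic spike at or before
    t_pre, and ("potentiation", dt > 0) with the earliest one after it.
    Both input trains must be strictly increasing.  An optional window drops
    pairings with |dt| > window_ms.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    for name, t in (("pre", pre), ("post", post)):
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"{name} spike times must be strictly increasing")
    pairs = []
    if post.size == 0:
        return pairs
    idx = np.searchsorted(post, pre, side="right")
    for k, t_pre in enumerate(pre):
        i = idx[k]
        if i > 0:
            dt = post[i - 1] - t_pre
            if window_ms is None or -dt <= window_ms:
                pairs.append((float(dt), "depression"))
        if i < post.size:
            dt = post[i] - t_pre
            if window_ms is None or dt <= window_ms:
                pairs.append((float(dt), "potentiation"))
    return pairs


class PlasticityLedger:
    """Spike-timing history plus pending per-synapse deltas (deferred model).

    The engine records every spike as it happens; ``finalize_until(T)``
    computes nearest-neighbor pairings for all presynaptic spikes with
    t <= T (vectorized over spikes × plastic fan-out) and accumulates the
    resulting Δw into the pending table; ``commit`` applies the pending
    additive updates to the weight array with clipping to [w_min, w_max].

    Finalization may be called at any step; the engine batches it at commit
    boundaries with T = t_commit - W, which is equivalent because deltas
    only take effect at commits.
    """

    def __init__(self, synapses, cfg: STDPConfig, max_delay_ms: int,
                 n_neurons: int | None = None):
        cfg.validate()
        self.cfg = cfg
        self.window = cfg.window(max_delay_ms)
        # pairing cutoff on |dt|: in arrival mode effective pre times lag by
        # up to max_delay, so the cutoff shrinks to keep deferred finalization
        # at T = t - window exact (no future spike can still pair)
        self.cutoff = (self.window - max_delay_ms if cfg.pairing == "arrival"
                       else self.window)
        pre = synapses.pre
        plastic = synapses.plastic
        n = n_neurons if n_neurons is not None else (int(pre.max()) + 1 if len(synapses) else 0)
        rows = np.flatnonzero(plastic)
        order = np.argsort(pre[rows], kind="stable")
        self.p_rows = rows[order]                  # plastic rows, by pre neuron
        self.p_post = synapses.post[self.p_rows]
        self.p_delay = synapses.delay_ms[self.p_rows]
        p_pre = pre[self.p_rows]
        self.p_indptr = np.searchsorted(p_pre, np.arange(n + 1))
        self.has_plastic_out = (self.p_indptr[1:] - self.p_indptr[:-1]) > 0
        self.pending = np.zeros(len(synapses))
        self._carry = (np.zeros(self.p_rows.size)
                       if cfg.delta_carry > 0.0 else None)
        # spike history (chunked appends) and retained sorted tail
        self._chunk_ids: list[np.ndarray] = []
        self._chunk_ts: list[np.ndarray] = []
        self._hist_i = np.empty(0, dtype=np.int64)
        self._hist_t = np.empty(0, dtype=np.int64)
        self._finalized_T = -1
        self.pairings_total = 0

    # -- recording ----------------------------------------------------------

    def record(self, fired_ids, t: int):
        """Append this step's spikes (all neurons; filtering happens later)."""
        fired_ids = np.asarray(fired_ids, dtype=np.int64)
        if fired_ids.size == 0:
            return
        if t <= self._finalized_T:
            raise ValueError("cannot record spikes at an already-finalized time")
        self._chunk_ids.append(fired_ids)
        self._chunk_ts.append(np.full(fired_ids.size, t, dtype=np.int64))

    # -- deferred pairing ---------------------------------------------------

    def _absorb_chunks(self):
        if self._chunk_ids:
            self._hist_i = np.concatenate([self._hist_i] + self._chunk_ids)
            self._hist_t = np.concatenate([self._hist_t] + self._chunk_ts)
            self._chunk_ids, self._chunk_ts = [], []

    def finalize_until(self, T: int) -> int:
        """Finalize pairings for presynaptic spikes with t <= T; returns count.

        A spike is safe to finalize once T >= t_spike (the caller guarantees
        no more spikes at times <= T will be recorded); with the engine's
        T = t - W the truncated pairing is exact.
        """
        self._absorb_chunks()
        if self._hist_t.size == 0 or T <= self._finalized_T:
            self._finalized_T = max(self._finalized_T, T)
            return 0
        hist_i, hist_t = self._hist_i, self._hist_t
        # sorted (neuron, time) keys over the full retained history
        order = np.lexsort((hist_t, hist_i))
        keys = (hist_i[order] << _TIME_BITS) | hist_t[order]
        key_i = hist_i[order]
        key_t = hist_t[order]
        # presynaptic spikes to finalize this call
        sel = (hist_t > self._finalized_T) & (hist_t <= T) & self.has_plastic_out[hist_i]
        ids, ts = hist_i[sel], hist_t[sel]
        n_pairs = 0
        if ids.size:
            starts = self.p_indptr[ids]
            counts = self.p_indptr[ids + 1] - starts
            rows = concat_ranges(starts, counts)     # into p_rows/p_post
            t0 = np.repeat(ts, counts)
            if self.cfg.pairing == "arrival":
                t0 = t0 + self.p_delay[rows]
            targets = self.p_post[rows]
            syn_rows = self.p_rows[rows]
            q = (targets << _TIME_BITS) | t0
            idx = np.searchsorted(keys, q, side="right")
            # potentiation: earliest post spike strictly after t0
            i_nxt = np.minimum(idx, keys.size - 1)
            dt = key_t[i_nxt] - t0
            valid = (idx < keys.size) & (key_i[i_nxt] == targets) & (dt <= self.cutoff)
            dw = np.where(valid,
                          self.cfg.A_plus * np.exp(np.clip(dt, 0, self.cutoff)
                                                   / -self.cfg.tau_plus_ms),
                          0.0)
            n_pairs += int(valid.sum())
            # depression: latest post spike at or before t0 (dt == 0 -> 0)
            i_prv = np.maximum(idx - 1, 0)
            mag = t0 - key_t[i_prv]
            validd = (idx > 0) & (key_i[i_prv] == targets) & (mag > 0) & (mag <= self.cutoff)
            dw -= np.where(validd,
                           self.cfg.A_minus * np.exp(np.clip(mag, 0, self.cutoff)
                                                     / -self.cfg.tau_minus_ms),
                           0.0)
            n_pairs += int(validd.sum())
            self.pending += np.bincount(syn_rows, weights=dw,
                                        minlength=self.pending.size)
        # evict history that can no longer partner any unfinalized spike
        keep = hist_t >= T - self.window
        self._hist_i, self._hist_t = hist_i[keep], hist_t[keep]
        self._finalized_T = T
        self.pairings_total += n_pairs
        return n_pairs

    # -- commit -------------------------------------------------------------

    def commit(self, weights: np.ndarray) -> int:
        """Apply pending deltas additively with clipping; returns #changed.

        With ``delta_carry`` > 0 a damped copy of the summed delta persists
        into later commits, and ``commit_drift`` adds a constant to every
        plastic weight per commit — the reference polychronization
        protocol's update (drift 0.01/s, carry 0.9); both default to 0,
        which is the memoryless additive commit.
        """
        rows = self.p_rows
        if rows.size == 0:
            return 0
        delta = self.pending[rows]
        if self._carry is not None:
            delta = delta + self._carry
            self._carry = self.cfg.delta_carry * delta
        new = np.clip(weights[rows] + delta + self.cfg.commit_drift,
                      self.cfg.w_min, self.cfg.w_max)
        changed = int(np.count_nonzero(new != weights[rows]))
        weights[rows] = new
        self.pending[rows] = 0.0
        return changed
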
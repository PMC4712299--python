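"""Event-driven spike delivery and post-synaptic current shaping.

Spikes emitted at step t through a synapse of delay d land in a ring buffer
bucket consumed exactly at step t + d; per-step synaptic drive is the
(linear, additive) bucket content passed through a selectable filter kernel
— delta (instantaneous), exponential decay, alpha function (unit peak at
t = tau), or a user-supplied finite kernel.

A current-based accumulation is the default; an optional conductance mode
splits deliveries by synapse sign into excitatory/inhibitory conductances
and scales drive by the respective driving force (E_rev - V).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def concat_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate integer ranges [s, s+c) — the CSR row-gather primitive."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    keep = counts > 0
    starts, counts = np.asarray(starts, dtype=np.int64)[keep], counts[keep]
    out = np.ones(total, dtype=np.int64)
    out[0] = starts[0]
    ends = np.cumsum(counts)
    out[ends[:-1]] = starts[1:] - (starts[:-1] + counts[:-1] - 1)
    return np.cumsum(out)


@dataclass
class PSCFilterConfig:
    """Post-synaptic current filter selection.

    kind: "delta" | "exp" | "alpha" | "custom"; tau_ms is the time constant
    for exp/alpha; custom_kernel is a finite per-ms coefficient list.  mode
    "current" feeds the filtered drive directly; "conductance" treats
    positive/negative weights as excitatory/inhibitory conductances with
    reversal potentials e_rev_exc / e_rev_inh.
    """

    kind: str = "delta"
    tau_ms: float = 5.0
    custom_kernel: tuple = ()
    mode: str = "current"
    e_rev_exc: float = 0.0
    e_rev_inh: float = -80.0

    def validate(self):
        if self.kind not in ("delta", "exp", "alpha", "custom"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind in ("exp", "alpha") and self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0 for exp/alpha filters")
        if self.kind == "custom":
            k = np.asarray(self.custom_kernel, dtype=float)
            if k.size == 0 or not np.all(np.isfinite(k)):
                raise ValueError("custom kernel must be finite and non-empty")
        if self.mode not in ("current", "conductance"):
            raise ValueError(f"unknown accumulation mode {self.mode!r}")


class SpikeEventBuffer:
    """Ring buffer over (max_delay + 1) slots of per-neuron pending weight.

    A spike enqueued at step t with delay d (1 <= d <= max_delay) is added
    to the bucket read at step t + d.  ``current_bucket`` returns the bucket
    for the buffer's own step counter; ``advance`` zeroes it and moves on.
    """

    def __init__(self, n_neurons: int, max_delay: int, lanes: int = 1):
        if max_delay < 1:
            raise ValueError("max_delay must be >= 1")
        self.n = n_neurons
        self.horizon = max_delay + 1
        self.lanes = lanes
        self.slots = np.zeros((lanes, self.horizon, n_neurons))
        self.t = 0
        self._consumed = False
        self.scheduled_total = 0.0
        self.consumed_total = 0.0

    def enqueue(self, targets, delays, weights, lane=None):
        """Schedule deliveries for the buffer's current step t; O(events)."""
        delays = np.asarray(delays, dtype=np.int64)
        if delays.size and (delays.min() < 1 or delays.max() >= self.horizon):
            raise ValueError("delay outside [1, max_delay]")
        slot = (self.t + delays) % self.horizon
        flat = slot * self.n + np.asarray(targets, dtype=np.int64)
        w = np.asarray(weights, dtype=np.float64)
        if lane is None:
            self.slots[0].ravel()[:] += np.bincount(flat, weights=w,
                                                    minlength=self.horizon * self.n)
        else:
            lane = np.asarray(lane)
            for ln in range(self.lanes):
                m = lane == ln
                if np.any(m):
                    self.slots[ln].ravel()[:] += np.bincount(
                        flat[m], weights=w[m], minlength=self.horizon * self.n)
        self.scheduled_total += float(w.sum())
        return int(w.size)

    def current_bucket(self, lane: int = 0) -> np.ndarray:
        return self.slots[lane, self.t % self.horizon]

    def consume(self, lane: int = 0) -> np.ndarray:
        """Read (a copy of) the current bucket, marking the step consumed."""
        out = self.current_bucket(lane).copy()
        self._consumed = True
        self.consumed_total += float(out.sum())
        return out

    def advance(self):
        """Zero the consumed bucket and move to the next step."""
        if not self._consumed:
            raise RuntimeError("advance() before the current step was consumed")
        self.slots[:, self.t % self.horizon, :] = 0.0
        self.t += 1
        self._consumed = False

    @property
    def in_flight(self) -> float:
        return self.scheduled_total - self.consumed_total


def enqueue_spikes(buffer: SpikeEventBuffer, fired_ids, indptr, post, weight,
                   delay, t=None, lane=None) -> int:
    """Schedule all outgoing synapses of the spiking neurons; returns Σ fanout.

    ``indptr``/``post``/``weight``/``delay`` form the pre-sorted CSR view of
    the synapse table.  ``t`` must equal the buffer's own step if given.
    """
    if t is not None and t != buffer.t:
        raise ValueError("enqueue time does not match buffer step")
    fired_ids = np.asarray(fired_ids, dtype=np.int64)
    if fired_ids.size == 0:
        return 0
    starts = indptr[fired_ids]
    counts = indptr[fired_ids + 1] - starts
    rows = concat_ranges(starts, counts)
    if rows.size == 0:
        return 0
    w = weight[rows]
    if lane is not None:
        # conductance lanes carry magnitudes; the sign is reintroduced by the
        # driving force (E_rev - V) at accumulation time
        w = np.abs(w)
    return buffer.enqueue(post[rows], delay[rows], w,
                          None if lane is None else lane[rows])


class InputAccumulator:
    """Per-neuron synaptic drive I_syn with optional filter state.

    One filter state per neuron (and per sign lane in conductance mode);
    deliveries within a step are pure sums, so they are order-independent.
    """

    def __init__(self, n_neurons: int, cfg: PSCFilterConfig):
        cfg.validate()
        self.cfg = cfg
        self.n = n_neurons
        self.lanes = 2 if cfg.mode == "conductance" else 1
        if cfg.kind == "exp":
            self._decay = float(np.exp(-1.0 / cfg.tau_ms))
            self._s = np.zeros((self.lanes, n_neurons))
        elif cfg.kind == "alpha":
            self._decay = float(np.exp(-1.0 / cfg.tau_ms))
            self._gain = float(np.e / cfg.tau_ms)
            self._a = np.zeros((self.lanes, n_neurons))
            self._y = np.zeros((self.lanes, n_neurons))
        elif cfg.kind == "custom":
            k = np.asarray(cfg.custom_kernel, dtype=float)
            self._kernel = k
            self._window = np.zeros((self.lanes, k.size, n_neurons))
            self._wpos = 0

    def _filtered(self, bucket: np.ndarray, lane: int) -> np.ndarray:
        kind = self.cfg.kind
        if kind == "delta":
            return bucket
        if kind == "exp":
            self._s[lane] = self._s[lane] * self._decay + bucket
            return self._s[lane]
        if kind == "alpha":
            # cascade of two identical first-order stages: impulse response
            # m·exp(-m/tau) per ms, scaled to unit peak at t = tau
            self._y[lane] = self._decay * (self._y[lane] + self._a[lane])
            self._a[lane] = self._decay * self._a[lane] + bucket
            return self._gain * self._y[lane]
        # custom finite kernel
        self._window[lane, self._wpos] = bucket
        k = self._kernel
        n = k.size
        idx = (self._wpos - np.arange(n)) % n
        out = np.tensordot(k, self._window[lane, idx], axes=(0, 0))
        return out

    def accumulate(self, buffer: SpikeEventBuffer, V: np.ndarray | None = None) -> np.ndarray:
        """Consume the buffer's current step and return per-neuron drive."""
        if self.cfg.mode == "current":
            out = self._filtered(buffer.consume(0), 0)
        else:
            g_exc = self._filtered(buffer.consume(0), 0)
            g_inh = self._filtered(self._consume_extra(buffer, 1), 1)
            if V is None:
                raise ValueError("conductance mode needs the membrane potential")
            out = g_exc * (self.cfg.e_rev_exc - V) + g_inh * (self.cfg.e_rev_inh - V)
        if self.cfg.kind == "custom":
            self._wpos = (self._wpos + 1) % self._kernel.size
        return out

    @staticmethod
    def _consume_extra(buffer: SpikeEventBuffer, lane: int) -> np.ndarray:
        out = buffer.current_bucket(lane).copy()
        buffer.consumed_total += float(out.sum())
        return out


def accumulate_inputs(buffer: SpikeEventBuffer, filt, V=None) -> np.ndarray:
    """Functional form: per-neuron I_syn for the buffer's current step.

    ``filt`` may be a PSCFilterConfig (a fresh accumulator is created — only
    meaningful for the memoryless delta filter) or an InputAccumulator whose
    state persists across steps.
    """
    if isinstance(filt, PSCFilterConfig):
        filt = InputAccumulator(buffer.n, filt)
    return filt.accumulate(buffer, V)
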
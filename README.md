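# spikesim

A millisecond-resolution spiking neural network simulator for computational
neuroscientists who want a small, fully deterministic, plain-text-friendly
engine for plasticity and network-rhythm experiments. It combines a
time-stepped (1 ms) two-phase loop — neuron state update, then synaptic
accumulation — with event-driven spike delivery over a conduction-delay
ring buffer, four classic point-neuron models (LIF, adaptive exponential
integrate-and-fire, Izhikevich, Hodgkin-Huxley), and nearest-neighbor
additive STDP with deferred batch weight commits.

The learning rule is the standard pair-based additive STDP

    Δw = +A₊·exp(−Δt/τ₊)    (Δt > 0,  pre before post)
    Δw = −A₋·exp(−|Δt|/τ₋)  (Δt < 0),      Δt = t_post − t_pre,

restricted to *presynaptic-centric nearest neighbors*: each presynaptic
spike pairs only with the closest postsynaptic spike on either side.
Weight changes are finalized only once a spike is older than a deferral
window (so no later spike could alter its pairings) and applied in batches
at fixed commit intervals, clipped to [w_min, w_max].

Three preset experiments exercise the stack end to end:

- **paired_stdp** — two mutually coupled aEIF neurons forced to fire 10 ms
  apart; the causal synapse potentiates to the upper bound, the
  anti-causal one decays to 0.
- **toroidal** — neurons on a 2-D torus with distance-dependent Gaussian
  connectivity, distance-proportional excitatory delays (≤ 16 ms) and 1 ms
  inhibitory delays.
- **polychronous** — 1000 Izhikevich neurons with heterogeneous 1–20 ms
  delays and STDP; with training, the population rhythm shifts from the
  slow 2–4 Hz band toward gamma, and time-locked "polychronous groups" can
  be triggered from anchor neurons.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from spikesim.experiments import run_paired_protocol

rec, traj = run_paired_protocol(cycles=6)
for t, wab, wba in zip(traj["t_ms"], traj["w_ab"], traj["w_ba"]):
    print(f"t={t:>5} ms  w_ab={wab:.5f}  w_ba={wba:.5f}")
```

prints (abridged)

```
t=   99 ms  w_ab=0.10000  w_ba=0.10000
t=  199 ms  w_ab=0.16065  w_ba=0.02722
t=  399 ms  w_ab=0.22131  w_ba=0.00000
t=  699 ms  w_ab=0.25000  w_ba=0.00000
t= 1702 ms  w_ab=0.25000  w_ba=0.00000
```

Each 250 ms stimulation cycle forces neuron a to fire 10 ms before
neuron b, adding +0.1·e^−½ ≈ +0.0607 to the causal weight w_ab and
−0.12·e^−½ ≈ −0.0728 to the anti-causal weight w_ba at each commit
(every 100 ms). After two cycles w_ba has hit the lower bound 0, and after
three w_ab has saturated at the upper bound 0.25 — the learning endpoint of
the paired-stimulation protocol.

The same machinery is scriptable from the shell:

```bash
spikesim build-network --preset polychronous --seed 1 --out net
spikesim run --config run.yaml --out-dir out/        # spikes.tsv, weights.tsv
spikesim analyze-rhythm out/spikes.tsv --band 1,150
spikesim find-groups --net trained --anchors 3 --out groups.json
```

and a PyNN-flavoured programmatic session is available in
`spikesim.pynn_like` (hardware-tuning setup keys from the original
platform vocabulary are accepted as no-ops, so legacy scripts run
unmodified).

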
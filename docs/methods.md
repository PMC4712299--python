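# Methods

## The simulation model

spikesim advances a network of point neurons on a fixed 1 ms grid with a
two-phase loop per step *t*:

1. **Neuron update.** The synaptic drive due at *t* is read from the delay
   ring buffer, passed through the post-synaptic current filter, and summed
   with external stimulation and noise; every neuron's state is then
   advanced one millisecond by its model's integrator, and threshold
   crossings are detected and reset.
2. **Synaptic accumulation.** Each spike emitted at *t* schedules its
   outgoing synaptic weights into the ring buffer bucket for *t + delay*
   (delays are integer milliseconds, minimum 1), is appended to the
   plasticity ledger, and — at fixed commit boundaries — pending plastic
   weight changes are applied in batch.

Because the minimum delay is 1 ms, the drive computed at step *t* can only
reflect spikes emitted at steps ≤ *t − 1*; there is no within-step
self-influence, and delivery is exact: a spike through a delay-*d* synapse
contributes to exactly the bucket consumed at *t + d*.

Synaptic accumulation is linear and additive. Weights are stored signed
(inhibitory synapses carry negative weights). Current-based accumulation is
the default; an optional conductance mode splits deliveries by sign into
two lanes of magnitudes and scales each by its driving force
(E_rev − V), with E_exc = 0 mV and E_inh = −80 mV by default.

### Neuron models

| model | state | default integrator | notes |
|---|---|---|---|
| LIF | V | RK4, 1 substep | τm dV/dt = −(V−EL) + R·I; reset V←Vr at Vth |
| aEIF | V, w | RK4, 2 substeps | C dV/dt = −gL(V−EL) + gL·ΔT·exp((V−VT)/ΔT) − w + I; τw dw/dt = a(V−EL) − w; reset V←Vr, w←w+b at Vpeak |
| Izhikevich | v, u | Euler, two 0.5 ms half-steps for v | v' = 0.04v² + 5v + 140 − u + I, u' = a(bv − u); reset v←c, u←u+d at 30 mV |
| HH | V, m, h, n | RK4, 20 substeps | canonical squid-axon rates; a spike is an upward crossing of 0 mV |

Units: aEIF uses pF/nS/mV/ms/pA (the standard parameter set C=281 pF,
gL=30 nS, EL=−70.6 mV, VT=−50.4 mV, ΔT=2 mV, a=4 nS, τw=144 ms, Vr=EL,
b=80.5 pA, Vpeak=0 mV is the default); LIF, Izhikevich and HH use the
dimensionless-current conventions of their original formulations, and all
injected amplitudes are interpreted in the target model's native input
units. The aEIF exponential argument is clamped at +20 before
exponentiation so trajectories stay finite between threshold crossing and
reset. All state is double precision; any NaN/Inf after a step raises an
error naming the first offending neuron.

The Izhikevich stepper advances v in two 0.5 ms Euler half-steps and u once
per millisecond, with detection/reset at the end of the step — the original
model's discretization — so the reset contract (v = c exactly; u = its
continuous update plus d) holds bit-exactly.

### Nearest-neighbor STDP with deferred batch commits

The learning rule is additive and pair-based with exponential windows,

    Δw = +A₊ · exp(−Δt/τ₊)   for Δt > 0,
    Δw = −A₋ · exp(−|Δt|/τ₋) for Δt < 0,      Δt = t_post − t_pre,

so pre-before-post potentiates. As printed, the depression branch would
grow without bound for large negative Δt; it is read as a magnitude with a
negative sign (the standard depression profile), and Δt = 0 contributes
nothing. Pairing is *nearest-neighbor and presynaptic-centric*: each
presynaptic spike pairs only with the latest postsynaptic spike at or
before it and the earliest one strictly after it; a postsynaptic spike may
appear in several pairings.

Weight changes are not applied online. Every spike enters a bounded
spike-timing table; once a presynaptic spike is older than the deferral
window W = max_delay + ⌈5·max(τ₊, τ₋)⌉ ms, no future spike can change its
pairings, so its Δw contributions are finalized into a pending per-synapse
table. Pending deltas are applied additively, with clipping to
[w_min, w_max], at fixed commit intervals (100 ms or 1000 ms in the
presets). Pairings with |Δt| beyond the window are truncated to zero; the
discarded exponential tail is below e⁻⁵ ≈ 0.7 % of the amplitude, and with
this truncation the deferred batch result equals an online implementation
of the same truncated rule *exactly*, which is what the equivalence tests
assert. Finalization is batched at commit boundaries (deltas only take
effect at commits, so per-step finalization would produce identical
results), making its cost one vectorized pass per commit instead of
per-spike work in the hot loop.

Two pairing-time conventions are supported. The default, `emission`,
measures Δt between somatic spike times. The `arrival` convention adds the
conduction delay to the presynaptic time first, so the afferents whose
spikes *arrive* just before the target fires are the ones that potentiate.
The polychronous preset uses `arrival`, the convention of the
polychronization literature it reproduces: delay-selection is the mechanism
that carves time-locked groups out of the delay-heterogeneous network, and
with emission timing the long-delay afferents of a causally driven target
are systematically mis-credited. In arrival mode the pairing cutoff shrinks
to 5·max(τ) (window minus max_delay) so that deferred finalization remains
exact. A precomputed Δw lookup table per integer |Δt| is available as an
optimization; the analytic formula is the source of truth and a test
compares the two.

Two further commit-stage options reproduce the weight-update conventions of
the polychronization protocol: a constant per-commit drift on plastic
weights (`commit_drift`, +0.01 per second there) and a damped carryover of
each commit's summed delta into later commits (`delta_carry`, 0.9 there),
which lets a pairing's effect build up over the following seconds instead
of acting once. Both default to 0, recovering the memoryless additive
commit of the printed rule.

Bounds are enforced at commits (not per pairing); within a commit batch the
additive deltas accumulate unclipped. Commit cadence therefore cannot
change the outcome on trajectories that never touch a bound, which is
tested, and the paired-stimulation endpoint is cadence-invariant because
both weights saturate at their bounds.

## Preset experiments

**Paired stimulation.** Two aEIF neurons with mutual 1 ms plastic synapses
(initial weight 0.1, bounds (0, 0.25)) are forced to fire by strong current
pulses (2000 pA for 5 ms, checked suprathreshold by a one-cycle dry run)
once per 250 ms cycle, neuron b lagging neuron a by 10 ms. With
A₊ = 0.1, A₋ = 0.12, τ± = 20 ms each cycle adds
+0.1·e^−½ ≈ +0.0607 to w_ab and −0.12·e^−½ ≈ −0.0728 to w_ba (cross-cycle
pairings at ±240 ms fall outside the deferral window; untruncated they are
below 10⁻⁶). w_ba reaches the lower bound 0 after two cycles and w_ab
saturates at 0.25 after three; ≥ 4 cycles are run for margin.

**Toroidal network.** One neuron per cell of a 2-D torus (row-major
0-based coordinates), 4:1 excitatory:inhibitory with inhibitory cells
chosen uniformly at random. Each neuron draws n_syn targets without
replacement with probability ∝ exp(−d²/2σ²) over the minimum-image
Euclidean distance (σ configurable for excitatory sources, 16 for
inhibitory). Sampling uses the Gumbel-top-k equivalence with successive
weighted draws without replacement, validated against exhaustive
enumeration by a chi-square test. Excitatory delays are proportional to
distance, scaled so the farthest possible pair maps to the 16 ms cap;
inhibitory delays are all 1 ms (fast local inhibition sustains network
rhythm). Weights are uniform in (0, 0.5), divided by n_syn/1000 so the
expected total drive is comparable across fan-out scenarios. The neuron
model defaults to Izhikevich (RS/FS).

**Polychronous network.** 1000 Izhikevich neurons — 800 regular-spiking
excitatory (a=0.02, b=0.2, c=−65, d=8) and 200 fast-spiking inhibitory
(a=0.1, d=2) — each with 100 outgoing synapses (ordered-pair connection
probability 100/999 ≈ 0.1). Excitatory synapses project anywhere, start at
weight 6, are plastic with w_max = 10 and carry uniform integer delays in
1–20 ms; inhibitory synapses project to excitatory neurons only, are fixed
at −5, non-plastic, with 1 ms delay (a switch restores random inhibitory
delays). Background drive injects amplitude 20 into one uniformly chosen
neuron every millisecond. Synapses use the delta filter (instantaneous
current). Commits run at 1 s intervals.

**Rhythm analysis** bins the population raster at 1 ms, removes the mean,
and estimates the power spectrum over a window (default 10 s) by Welch
averaging of 1 s segments. The dominant rhythm is the strongest narrowband
peak *above the aperiodic background* — power divided by a running-median
estimate of the local spectrum — within a stated band. Trained networks of
this kind carry substantial broadband slow-envelope power alongside the
oscillation, so a raw power argmax reads the envelope rather than the
rhythm; normalizing by the aperiodic background (standard practice in
neural spectral analysis) identifies the oscillatory peak in both regimes,
and reduces to the obvious answer (the comb line, the delta burst
frequency) whenever a single narrowband rhythm dominates. The raw
periodogram and plain argmax remain available as options. The untrained preset oscillates
in the 2–4 Hz band; after roughly an hour of model time with STDP the
dominant rhythm moves to the 30–100 Hz gamma band. The desk-scale runs here
use 3600 s of model time (the original protocol runs 24 h); the group
census of the full-scale study is not asserted — instead a constructed
chain with known delays must reproduce cumulative-delay firing times
exactly, and a trained network must yield more groups than its untrained
twin under an identical search.

**Group search.** For each excitatory target, afferents with weight
≥ 0.95·w_max are candidate anchors. Three anchors (the strongest; more
combinations optional) are stimulated with offsets max_delay − delay so
their spikes arrive at the target simultaneously, the network is simulated
for a 150 ms quiet window (no noise, plasticity off), and the triggered
sequence is kept as a group if it recruits ≥ 7 distinct neurons. Anchor
count, threshold and minimum size follow the polychronization literature's
conventions; none are stated by the protocol itself.

## What the synthetic presets do and do not show

All inputs are generated programmatically from printed parameters; there is
no recorded data. The presets reproduce *mechanisms* — timing-dependent
weight selection, delay-selected time-locked groups, a learning-driven
rhythm transition — under idealized conditions: homogeneous parameters
within populations, Bernoulli/uniform connectivity, stationary background
drive, and exact 1 ms alignment of all events. Passing tests therefore
demonstrate correctness of the engine and the rule, and qualitative
agreement with the published network phenomena; they do not calibrate any
model to biological recordings, and quantities that depend on the 24 h
training horizon (e.g. the absolute number of groups) are out of scope at
desk scale.

## Numerical and design choices

- Delays are integers in milliseconds; samplers yielding fractions round to
  nearest with a floor of 1. Self-connections and multi-edges are never
  generated.
- A single run seed feeds named substreams (connectivity, noise, stimulus)
  via `SeedSequence(seed, spawn_key=(crc32(name),))`, so changing one
  consumer does not perturb the others and runs are bit-reproducible; a
  cloned engine (deep copy of state arrays, ring buffer, filter state,
  ledger and RNG streams) resumed from a split point matches an unbroken
  run exactly.
- Deliveries within a step are pure sums (order-independent); the ring
  buffer zeroes each bucket after consumption and refuses double advances.
- The alpha filter is normalized to unit peak at t = τ and implemented as a
  cascade of two identical first-order stages (impulse response
  m·e^(−m/τ)·e/τ at integer m).
- Filter state is per neuron (one lane per sign in conductance mode), not
  per synapse, keeping memory linear in neurons.
- Spike rasters, weight tables and network edge lists are plain TSV with
  headers; network headers are JSON. Writers emit deterministic bytes.
- Wall-clock-dependent metrics (spike delivery rate) are reported in run
  logs but never asserted in tests.
- Hardware-oriented setup keys from the original platform vocabulary
  (parallelism, clock frequency, FPGA count) are accepted in configs and
  the PyNN-style `setup()` for script compatibility, logged, and ignored.

## Known limitations

- The engine is single-threaded; the 3600 s polychronous training run takes
  on the order of ten minutes of wall time.
- Short-term plasticity, triplet STDP, multiplicative STDP, conductance
  saturation, gap junctions and multi-compartment neurons are not
  implemented; all-to-all pairing exists only as a test oracle.
- HH spike detection (upward 0 mV crossing) counts at most one spike per
  1 ms step.
- In conductance mode both lanes share one filter time constant; per-sign
  time constants are not supported.
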
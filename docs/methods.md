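# Methods

This note documents the models implemented in `spikemap`, the conventions
and numerical choices that define its behaviour, the provenance of its
default parameters, and what the test suite does and does not establish.

## Neuron and input model

Neurons are current-based leaky integrate-and-fire units with exponential
synapses.  Per receptor `r`, the synaptic current decays by
`exp(-dt/tau_syn[r])` each step and then receives the weight drained from
the ring buffer (weights are in current units; an entire postsynaptic
current transient is the drained weight filtered through the synaptic
exponential).  The membrane then integrates the *total* current, held
constant over the step, with the exact exponential propagator

    v' = v_rest + I·R + (v − v_rest − I·R) · exp(−dt/tau_m)

so that under constant input the iterated update reproduces the analytic
solution `v(t) = v_rest + I·R·(1 − e^(−t/tau_m))` to machine precision
(the suite checks 1e−9 mV).  Holding the current constant within a step
(rather than co-integrating the synapse/membrane pair exactly) is a
first-order splitting; it was chosen because it makes the membrane update
testable against the closed form in isolation and matches common practice
on fixed-step neuromorphic kernels.  Whether the reference hardware uses
exact or Euler integration is not documented; no numerical equivalence to
any particular hardware binary is claimed.

Threshold crossing emits a spike, resets `v` and clamps it at `v_reset`
for `round(t_refrac/dt)` steps.  Poisson sources spike per step with
`p = 1 − exp(−rate·dt)`; background input is delivered as current
(`counts × weight` per neuron per step), matching the current-input
processor design rather than routed spike events.

## Time and delay conventions

Time step `k` advances the network from `k·dt` to `(k+1)·dt`; spikes and
flushes are timestamped `(k+1)·dt`.  Routing consumes one step: an event
emitted at `t` is processed by synapse cores during the following step.
A projection delay of `d ≥ 1` steps therefore splits into 1 step of
transit plus `d − 1` ring-buffer slots, so the postsynaptic membrane feels
the input at exactly `t + d·dt`.  All delay is modelled postsynaptically
(dendritically), which guarantees presynaptic events can be processed
immediately on arrival; the minimum delay is 1 step and the default ring
depth is 16 steps (one extra physical slot prevents a maximal delay from
aliasing the slot being drained).

Ring-buffer accumulation is integer fixed point (16 fraction bits,
saturated to 32-bit range at drain).  Integer addition commutes and
associates, so a step's inserts drain identically under any ordering and
any split of the afferent synapses across cores — this, together with a
canonical (key-sorted) event-processing order and counter-based random
streams keyed by `(seed, population, step)` for sources/background and
`(seed, projection, presynaptic id)` for connectivity, is what makes
rasters and final weights bit-identical across partitionings.  The
canonical event order replaces hardware arrival nondeterminism and is an
artifact convention, as is the choice to saturate at drain time (exact
per-add saturation would be order-dependent for mixed-sign inputs).

## Deferred plasticity

Plastic synapses implement all-to-all pair-based STDP with additive weight
dependence: potentiation `a₊·s_i·exp(−Δt/τ₊)` at each post spike against
the pre trace, depression `a₋·s_j·exp(−Δt/τ₋)` at each pre spike against
the post trace, hard-clipped to `[0, w_max]`.  Updates are deferred to row
visits: each row stores `(t_lastSpike, s_i, t_lastUpdate)`; each
postsynaptic neuron keeps a fixed-capacity (default 10) circular queue of
`(t_j, s_j)` entries, where `s_j` includes the entry's own spike.  On a
row visit at time `t`, entries in `(t_lastUpdate, t]` are replayed as
potentiation; if the visit is a real spike (not a flush), depression
against the most recent entry at or before `t` follows, the updated weight
enters the ring buffer at the synapse's delay, and the pre-side header
advances.  A flush replays history and advances `t_lastUpdate` only.

Conventions worth stating exactly:

- *Simultaneous pre/post at the same `t`*: the post entry is recorded
  first and replayed before the pre update, so the Δt = 0 interaction
  contributes `a₊·s_i` and `a₋·s_j` with no decay.
- *Flush emission*: every neuron presynaptic to a plastic projection
  monitors its own silence; when `t − max(last spike, last flush)` reaches
  `bufferSize × 1000/max_rate` ms, a flush key (the neuron id with the
  flag bit set) is emitted and the timer re-arms.  `max_rate` is the
  network-wide maximum firing rate declared in the spec; declaring it
  *above* the true maximum only makes flushing more frequent and is safe.
- *Lost entries*: the queue overwrites its oldest entry when full.  An
  overwrite counts as a lost entry only if the entry had not yet been
  consumed — i.e. its time exceeds the minimum `t_lastUpdate` over the
  rows sharing the queue (tracked as a per-queue watermark).  With every
  presynaptic neuron flushing on schedule and true rates at or below
  `max_rate`, no needed entry is ever overwritten; losses are always
  counted and reported, never silent.

The suite verifies that the deferred algorithm with unbounded history
equals an independently implemented online all-pairs oracle to machine
precision on 1000 random spike-train pairs, and that the capacity-10 queue
with flushes enabled is lossless and oracle-exact at a 1 Hz pre / 100 Hz
post rate skew, while disabling flushes loses entries and shifts the
result.

## Cost models and partitioning

All cost constants live in `CostConstants` (200 MHz clock; standard
mapping: 181 cycles/neuron/step and 21 cycles/event static, 187 and
`131 + 31h` plastic; synapse-centric: 15 cycles/event static and
`107 + 30h` plastic).  The static standard-mapping estimate is capped at
the practical 256 neurons/core.  `h` defaults to 1 (pre and post firing at
similar rates) and the planning presynaptic rate to 3 Hz (the cortical
8000-input × 3 Hz = 24 kHz assumption); both are overridable.

The per-row overheads of the synapse-centric processors
(`sc_static_per_row = 800`, `sc_stdp_per_row = 1500` cycles) are not
directly profiled figures: they are calibrated once to the admissible
intervals implied by the published processor counts (static: 2 processors
at 100% connectivity and 3 at 10% for 1024 neurons at 24 kHz, bounding the
overhead to roughly (547, 964]; plastic: 9 at 100%, 10 at 20%, infeasible
for 10 at 10% for 512 neurons, bounding it to roughly (1318, 2637]).  Both
are exposed in configuration.

`count_synapse_processors` returns the minimal `k` with
`(events/s · c_e + rows/s · c_row)/k ≤ clock`, events and rows dividing
evenly; a single row whose visit cost exceeds one step budget is
indivisible and raises an infeasibility error.  The partitioner splits
each population's afferents by synapse type (receptor × plasticity rule),
postsynaptically at 1024 (static) / 512 (plastic) neurons, and
presynaptically by this count.  Neuron processors hold 1024 neurons,
halved to 512 when a 1024-neuron group needs ≥ 4 synapse processors or a
shared-buffer group would exceed the 16 cores of one chip.  The
population's synapse-core total is the neuron-core-aligned count
`ceil(neuron_cores × k_group × size/1024)`; when a trailing partial post
window would demand one more chunk than that count admits, the partial
window is absorbed into its predecessor (a short window has ring-memory
margin to spare).  Current-input cores are allocated one per neuron core
for populations with Poisson background.

`audit_allocation` converts a run's recorded per-core event/row counts
into cycles per step and flags any step over `clock × dt`.

## Benchmark fixtures and parameter provenance

- **Poisson benchmark**: `n_sources = ceil(μ_input/(source_rate ×
  connectivity))` independent 10 Hz sources per population, so each neuron
  sees `μ_input` events/s in expectation.  DC drive for target
  postsynaptic rates is found by bisection (`calibrate_dc_drive`).
- **Vogels–Abbott**: neuron and weight parameters are adopted from the
  published CUBA benchmark literature, not derived here: `tau_m` 20 ms,
  rest −49 mV (above the −50 mV threshold, so the network is
  intrinsically active), reset −60 mV, refractory 5 ms, `tau_syn` 5/10 ms,
  weights 0.27/−4.5 current units at R = 20, delay 1 step.  Membrane
  potentials start uniform in [reset, threshold] and a 50 ms DC kick to
  10% of the excitatory cells desynchronises startup.  At 10,000 neurons
  and 2% connectivity the simulated network settles near 2–3 Hz; the
  suite asserts only the broad 1–100 Hz plausibility band, since no
  reference firing rate is published for this configuration.
- **Modular attractor**: structural constants are fixed (1000 excitatory
  cells in ten 100-neuron minicolumns plus 250 inhibitory cells per
  hypercolumn).  The two plastic excitatory projection classes are STDP
  stand-ins chosen to exercise heterogeneous rules on one population — a
  short-window rule (τ± = 10 ms) on a fast receptor and a long
  asymmetric-window rule (τ₊ = 150 ms, τ₋ = 50 ms, potentiation-dominant)
  on a slow receptor — not a reproduction of the Bayesian confidence
  propagation rule used in the original attractor work, whose equations
  are defined elsewhere.  The suite checks the qualitative signature of
  sequence training (forward cross-minicolumn weights exceed backward),
  not any published weight matrix.

## Problem sizes used in the checks

Cost-model and partitioning checks run at the full published sizes
(including the 80,000-neuron allocation — partitioning is analytic and
cheap).  Simulation-based checks use: 1000 random pre/post pairs × 10 s
for plasticity equivalence; a 2,000-neuron mixed plastic/static network
for 300 ms × 4 mappings for partition invariance; the 10,000-neuron
Vogels–Abbott network for 500 ms for sustained activity; one hypercolumn
for two sequence repetitions for attractor directionality.  These sizes
were chosen as the smallest at which each property is non-trivially
exercised.

## What the synthetic benchmarks do and do not show

The generators emulate the *load structure* the mapping was designed for
(event rates, row lengths, rate skews, heterogeneous rules), under ideal
Poisson/Bernoulli statistics, homogeneous parameters within populations
and stationary rates.  They do not model hardware packet loss, router
congestion, DMA latency, memory-bandwidth saturation, or fixed-point
neuron arithmetic beyond the ring buffers — costs are *accounted* by the
model, not enacted, so measured hardware throughput and bandwidth curves
are outside what this package can or does reproduce.  Passing tests
establish the internal consistency of the algorithms and cost models, not
timing fidelity to any physical machine.

## Known limitations

- Current-based exponential synapses only; no conductance synapses,
  adaptive thresholds or spike-frequency adaptation.
- The standard-mapping 0.1 ms capacities are empirical on hardware and
  are not predicted by the reconstructed cost model (it yields 86 where
  84 is reported); nothing downstream depends on them.
- No placement onto a physical chip/board topology or routing tables;
  "chip" exists only as the 16-core shared-buffer constraint.
- Event-driven row processing is pure Python per plastic row; large
  plastic networks simulate slowly (static paths are vectorised).
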
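# spikemap

**Synapse-centric mapping and simulation of spiking neural networks on
many-core neuromorphic hardware.**

Cortical neurons receive on the order of 8000 synaptic inputs each, firing
at a few Hz — roughly 24 kHz of synaptic events per neuron.  On
distributed, real-time neural simulators built from small 200 MHz cores
(each of which must finish its share of the network within every
simulation time step), the conventional mapping places a slice of neurons
*and their entire afferent synaptic column* on each core.  As connectivity
gets sparser, the synaptic matrix rows fetched per spike get shorter, the
fixed per-row overhead (DMA setup, interrupt servicing, loop setup)
dominates, and throughput collapses — the only remedy, shrinking the
neuron slice, shortens the rows further.

`spikemap` is a software model of the *synapse-centric* alternative: the
synaptic matrix is split **row-wise** across dedicated *synapse
processors* (by synapse type, then postsynaptically at ring-buffer /
history memory limits of 1024 static or 512 plastic neurons, then
presynaptically by processing cost), while *neuron processors* only sum
per-step input buffers and integrate membrane dynamics, and
*current-input processors* deliver Poisson background as pre-weighted
current vectors.  The package provides:

- **Cycle-cost models.**  Standard mapping supports
  `N = clock / (c_n/dt + c_e(h)·μ)` neurons per core with per-neuron cost
  `c_n` (181 cycles static, 187 plastic), per-event cost `c_e`
  (21 cycles static, `131 + 31h` plastic, where `h` is the expected
  postsynaptic-history length replayed per row visit) and per-neuron input
  rate `μ`.  A synapse processor handles
  `μ_events = clock / (c_e + c_row/L)` events/s at mean row length `L`
  (`c_e` = 15 static, `107 + 30h` plastic), which is what makes sparse
  connectivity expensive.
- **A partitioner** that turns a declarative network description into an
  allocation of neuron / synapse / current-input virtual cores, with the
  shared-buffer (16 cores per chip) and neuron-processor-halving rules,
  plus a real-time feasibility audit in clock cycles per step.
- **An executable engine** that runs the partitioned network as
  communicating virtual cores: event-driven synaptic row processing,
  fixed-point (16 fraction bits) ring-buffer delay accumulation, deferred
  pair-based STDP with a fixed 10-entry postsynaptic history and *flush
  events* (a neuron silent for `bufferSize` maximum-rate interspike
  intervals re-emits its id with a flag bit, forcing efferent rows to
  replay history before the queue overflows).  Because ring-buffer
  accumulation is integer and event ordering is canonical, **spike rasters
  and final weights are bit-identical across any partitioning of the same
  network** — the central correctness property of the mapping.
- **Benchmark generators**: the 24 kHz Poisson-input benchmark (static or
  STDP), the Vogels–Abbott random excitatory/inhibitory network at 10,000
  (2% connectivity) and 80,000 (10%) neurons, and a modular-attractor
  skeleton (hypercolumns of ten 100-neuron minicolumns plus shared
  inhibition) carrying two differently configured STDP rules on one
  population.

## Worked example

Build the 10,000-neuron Vogels–Abbott network description and partition it
synapse-centrically:

```sh
$ spikemap build vogels_abbott --size 10000 --p 0.02 --seed 1 -o va10k.yaml
wrote va10k.yaml: 10000 neurons, 4 projections
$ spikemap partition va10k.yaml
scheme: synapse_centric   dt: 1.0 ms
core role          population   slice          kind    est cycles/step
   0 neuron        exc          [0,1024)       -                185344
   1 neuron        exc          [1024,2048)    -                185344
...
totals: 10 neuron + 20 synapse + 0 current-input = 30 cores
```

Ten neuron processors (1024 neurons each, 185,344 of the 200,000-cycle
step budget) plus twenty synapse processors — one excitatory-type and one
inhibitory-type per 1024-neuron group — for 30 cores in total, against 40
for the standard mapping (`--scheme standard`).  Running a scaled-down
instance end to end:

```sh
$ spikemap benchmark vogels_abbott --size 1000 --p 0.02 --seed 1 --duration 200
{
 "benchmark": "vogels_abbott",
 "neurons": 1000,
 "cores": {"scheme": "synapse_centric", "neuron_cores": 2,
           "synapse_cores": 4, "current_input_cores": 0, "total_cores": 6},
 "spikes": 2590,
 "mean_rate_hz": 12.95,
 "flushes": 0,
 "lost_history_entries": 0
}
```

The network self-sustains at ~13 Hz; no plastic rows, hence no flushes.
`spikemap simulate` additionally writes the spike raster, plastic-weight
triplets and the per-core feasibility audit.

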
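# Network description file

`spikemap build` emits — and `partition`/`simulate` consume — a YAML
document mirroring the in-memory network spec one-to-one.  A commented
example:

```yaml
dt: 1.0            # simulation time step, ms
duration: 500.0    # default run length, ms
max_rate: 200.0    # network-wide max firing rate, Hz (sets flush threshold)
seed: 1            # master seed for connectivity, sources, background
max_delay: 16      # ring-buffer depth, steps (delays must fit)

populations:
  - name: exc
    size: 8000
    params:                    # leaky integrate-and-fire parameters
      tau_m: 20.0              # membrane time constant, ms
      v_rest: -49.0            # mV
      v_thresh: -50.0          # mV
      v_reset: -60.0           # mV
      t_refrac: 5.0            # ms
      r_membrane: 20.0         # mV per current unit
      i_offset: 0.0            # constant bias current
      tau_syn: {exc: 5.0, inh: 10.0}   # per-receptor current decay, ms
    v_init: [uniform, -60.0, -50.0]    # optional initial membrane range
    background:                # optional Poisson current input
      rate: 10.0               # Hz per source
      n_sources_per_neuron: 120
      weight: 0.02             # current units per source spike
      receptor: exc
  - name: sources              # a Poisson spike-source population
    size: 2400
    source_rate: 10.0          # Hz; routed as spikes, no dynamics

projections:
  - pre: exc
    post: exc
    p: 0.02                    # independent per-pair probability
    weight: 0.27               # scalar, or [uniform, lo, hi]
    delay: 1                   # steps, or [uniform_int, lo, hi]
    receptor: exc
    plasticity: stdp           # omit for static synapses
    # allow_self: true         # self-connections (default excluded)
    # pairs: [[0, 3], [1, 2]]  # explicit pair list instead of p

plasticity:                    # named pair-based STDP configurations
  stdp:
    tau_plus: 20.0             # potentiation window, ms
    tau_minus: 20.0            # depression window, ms
    a_plus: 0.01
    a_minus: 0.012
    w_max: 0.05                # hard upper clip; lower clip is w_min
    w_min: 0.0

stimuli:                       # optional time-windowed DC injections
  - population: exc
    start_ms: 0.0
    stop_ms: 50.0
    current: 0.3
    lo: 0                      # neuron range [lo, hi)
    hi: 800
```

Multiple plasticity configurations may target the same postsynaptic
population through separate projections (heterogeneous learning rules);
the partitioner places each rule on its own synapse processors.
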
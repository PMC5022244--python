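"""Programmatic generators for the benchmark networks.

Three families of fixture:

* **Poisson benchmark** -- a population of LIF neurons, each receiving a
  configurable aggregate Poisson input rate (the cortical reference point
  is 8000 inputs x 3 Hz = 24 kHz per neuron) delivered by many independent
  10 Hz sources through a projection of configurable sparsity, optionally
  plastic.  This is the workload the synapse-processor cost models are
  stated for.
* **Vogels-Abbott network** -- the widely used random CUBA network of
  excitatory and inhibitory LIF populations (80/20 split, all four
  projections at one connection probability).  Neuron and weight parameters
  are not part of this package's contribution; they follow the published
  benchmark literature (current-based exponential synapses, resting
  potential slightly above threshold so the network is self-active) and are
  exposed as overridable defaults.
* **Modular attractor skeleton** -- hypercolumns of 10 competing 100-neuron
  excitatory minicolumns plus shared inhibition, with *two* plastic
  excitatory projection classes carrying differently configured STDP rules
  (a short-window "AMPA-like" rule and a long, asymmetric-window
  "NMDA-like" rule), exercising heterogeneous plasticity on one
  population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import Engine
from .network import (BackgroundInputSpec, NetworkSpec, NeuronParams,
                      Population, Projection, Stimulus)
from .plasticity import PlasticityConfig


@dataclass
class BenchmarkSpec:
    """Parameters of a Poisson-input synapse-processor benchmark."""

    kind: str = "poisson_static"       # poisson_static | poisson_stdp
    n_post: int = 1024
    connectivity: float = 1.0
    mu_input: float = 24000.0          # target synaptic events/s per neuron
    source_rate: float = 10.0          # Hz per Poisson source
    postsynaptic_drive: float = 0.0    # DC current for target post rates
    weight: float = 0.001
    delay: int = 1
    seed: int = 1

    @property
    def n_sources(self) -> int:
        """Sources needed so each neuron sees ``mu_input`` events/s."""
        return math.ceil(self.mu_input / (self.source_rate * self.connectivity))


def make_poisson_benchmark(bench: BenchmarkSpec) -> NetworkSpec:
    """Build the Poisson-input benchmark network.

    Each of ``n_post`` LIF neurons receives on average ``mu_input``
    synaptic events per second from independent ``source_rate`` Hz Poisson
    sources connected with probability ``connectivity``.  ``poisson_stdp``
    makes the projection plastic.
    """
    if bench.mu_input < 0 or bench.connectivity <= 0 or bench.connectivity > 1:
        raise ValueError("need mu_input >= 0 and connectivity in (0, 1]")
    params = NeuronParams(tau_m=20.0, v_rest=-65.0, v_thresh=-50.0,
                          v_reset=-65.0, t_refrac=2.0, r_membrane=20.0,
                          tau_syn={"exc": 5.0},
                          i_offset=bench.postsynaptic_drive)
    pops = [Population("post", bench.n_post, params=params)]
    projections = []
    configs = {}
    if bench.mu_input > 0:
        pops.append(Population("sources", bench.n_sources,
                               source_rate=bench.source_rate))
        plasticity = None
        if bench.kind == "poisson_stdp":
            plasticity = "stdp"
            configs["stdp"] = PlasticityConfig(w_max=2 * bench.weight)
        projections.append(Projection(
            pre="sources", post="post", p=bench.connectivity,
            weight=bench.weight, delay=bench.delay, receptor="exc",
            plasticity=plasticity))
    return NetworkSpec(populations=pops, projections=projections,
                       plasticity_configs=configs, dt=1.0, duration=1000.0,
                       max_rate=100.0, seed=bench.seed)


# ---------------------------------------------------------------------------
# Vogels-Abbott CUBA network
# ---------------------------------------------------------------------------

#: CUBA parameters adopted from the published benchmark literature (external
#: provenance; not derived in this package).  Currents are in nA with a
#: 20 MOhm input resistance; the -49 mV resting potential sits above the
#: -50 mV threshold so the network is intrinsically active.
VOGELS_ABBOTT_DEFAULTS = dict(
    tau_m=20.0, v_rest=-49.0, v_thresh=-50.0, v_reset=-60.0, t_refrac=5.0,
    r_membrane=20.0, tau_syn_exc=5.0, tau_syn_inh=10.0,
    w_exc=0.27, w_inh=4.5, delay=1,
)


def make_vogels_abbott(n_total: int = 10000, p: float = 0.02,
                       seed: int = 1, duration: float = 500.0,
                       stimulus_ms: float = 50.0,
                       overrides: Optional[dict] = None) -> NetworkSpec:
    """Build the Vogels-Abbott random network at a given size and sparsity.

    ``n_total`` splits 80/20 into excitatory and inhibitory populations;
    all four projections use connection probability ``p`` (self-connections
    excluded).  Membrane potentials start uniformly between reset and
    threshold and an initial DC stimulus to part of the excitatory
    population kicks activity, after which the network sustains itself.
    """
    if n_total % 5 != 0:
        raise ValueError("n_total must split 80/20 into whole neurons")
    cfg = dict(VOGELS_ABBOTT_DEFAULTS)
    cfg.update(overrides or {})
    n_exc = n_total * 4 // 5
    n_inh = n_total - n_exc
    params = NeuronParams(
        tau_m=cfg["tau_m"], v_rest=cfg["v_rest"], v_thresh=cfg["v_thresh"],
        v_reset=cfg["v_reset"], t_refrac=cfg["t_refrac"],
        r_membrane=cfg["r_membrane"],
        tau_syn={"exc": cfg["tau_syn_exc"], "inh": cfg["tau_syn_inh"]})
    v0 = ("uniform", cfg["v_reset"], cfg["v_thresh"])
    pops = [Population("exc", n_exc, params=params, v_init=v0),
            Population("inh", n_inh, params=params, v_init=v0)]
    projections = []
    for pre, w, rec in (("exc", cfg["w_exc"], "exc"),
                        ("inh", -cfg["w_inh"], "inh")):
        for post in ("exc", "inh"):
            projections.append(Projection(
                pre=pre, post=post, p=p, weight=w, delay=cfg["delay"],
                receptor=rec))
    stimuli = [Stimulus("exc", 0.0, stimulus_ms, current=0.3,
                        lo=0, hi=max(1, n_exc // 10))]
    return NetworkSpec(populations=pops, projections=projections, dt=1.0,
                       duration=duration, max_rate=200.0, seed=seed,
                       stimuli=stimuli)


# ---------------------------------------------------------------------------
# Modular attractor skeleton
# ---------------------------------------------------------------------------

EXC_PER_HYPERCOLUMN = 1000
INH_PER_HYPERCOLUMN = 250
MINICOLUMNS_PER_HYPERCOLUMN = 10
MINICOLUMN_SIZE = EXC_PER_HYPERCOLUMN // MINICOLUMNS_PER_HYPERCOLUMN


def make_modular_attractor(n_hypercolumns: int = 1, seed: int = 1,
                           p_plastic: float = 0.2,
                           p_static: float = 0.2) -> NetworkSpec:
    """Build the modular attractor skeleton with heterogeneous plasticity.

    Each hypercolumn holds 1000 excitatory cells in 10 minicolumns of 100
    plus 250 inhibitory cells.  The excitatory population carries two
    plastic projection classes with distinct rules on separate receptors:
    an "AMPA-like" short symmetric-window rule (fast recurrent
    sharpening) and an "NMDA-like" long asymmetric-window rule (forward
    sequence binding), alongside static excitatory->inhibitory and
    inhibitory->excitatory connectivity.
    """
    if n_hypercolumns < 1:
        raise ValueError("need at least one hypercolumn")
    n_exc = n_hypercolumns * EXC_PER_HYPERCOLUMN
    n_inh = n_hypercolumns * INH_PER_HYPERCOLUMN
    exc_params = NeuronParams(
        tau_m=20.0, v_rest=-70.0, v_thresh=-55.0, v_reset=-70.0,
        t_refrac=2.0, r_membrane=20.0,
        tau_syn={"ampa": 5.0, "nmda": 100.0, "gaba": 10.0})
    inh_params = NeuronParams(
        tau_m=10.0, v_rest=-70.0, v_thresh=-55.0, v_reset=-70.0,
        t_refrac=1.0, r_membrane=20.0, tau_syn={"ampa": 5.0})
    bg = BackgroundInputSpec(rate=10.0, n_sources_per_neuron=100,
                             weight=0.012, receptor="ampa")
    pops = [Population("exc", n_exc, params=exc_params, background=bg),
            Population("inh", n_inh, params=inh_params)]
    configs = {
        "ampa_stdp": PlasticityConfig(tau_plus=10.0, tau_minus=10.0,
                                      a_plus=0.002, a_minus=0.002,
                                      w_max=0.05),
        "nmda_stdp": PlasticityConfig(tau_plus=150.0, tau_minus=50.0,
                                      a_plus=0.002, a_minus=0.001,
                                      w_max=0.02),
    }
    projections = [
        Projection("exc", "exc", p=p_plastic, weight=0.0, delay=1,
                   receptor="ampa", plasticity="ampa_stdp"),
        Projection("exc", "exc", p=p_plastic, weight=0.0, delay=1,
                   receptor="nmda", plasticity="nmda_stdp"),
        Projection("exc", "inh", p=p_static, weight=0.02, delay=1,
                   receptor="ampa"),
        Projection("inh", "exc", p=p_static, weight=-0.12, delay=1,
                   receptor="gaba"),
    ]
    return NetworkSpec(populations=pops, projections=projections,
                       plasticity_configs=configs, dt=1.0, duration=1000.0,
                       max_rate=100.0, seed=seed)


def make_sequence_stimuli(n_hypercolumns: int, n_repeats: int = 3,
                          dwell_ms: float = 25.0, gap_ms: float = 0.0,
                          current: float = 2.0) -> list:
    """Training stimuli: activate minicolumns 0..9 of every hypercolumn in
    sequence, repeated ``n_repeats`` times."""
    stimuli = []
    t = 0.0
    for _ in range(n_repeats):
        for m in range(MINICOLUMNS_PER_HYPERCOLUMN):
            for h in range(n_hypercolumns):
                lo = h * EXC_PER_HYPERCOLUMN + m * MINICOLUMN_SIZE
                stimuli.append(Stimulus("exc", t, t + dwell_ms, current,
                                        lo=lo, hi=lo + MINICOLUMN_SIZE))
            t += dwell_ms + gap_ms
    return stimuli


def minicolumn_of(exc_index: int) -> int:
    """Minicolumn index (within its hypercolumn) of an excitatory cell."""
    return (exc_index % EXC_PER_HYPERCOLUMN) // MINICOLUMN_SIZE


# ---------------------------------------------------------------------------
# Drive calibration
# ---------------------------------------------------------------------------

def calibrate_dc_drive(bench: BenchmarkSpec, target_rate: float,
                       lo: float = 0.0, hi: float = 2.0,
                       duration: float = 500.0, tol: float = 1.0,
                       max_iter: int = 12) -> float:
    """Bisect the DC drive current that yields a target postsynaptic rate.

    Runs short simulations of the benchmark at candidate drives until the
    measured population rate is within ``tol`` Hz of ``target_rate``.
    """
    def rate_at(drive: float) -> float:
        b = BenchmarkSpec(**{**bench.__dict__, "postsynaptic_drive": drive})
        spec = make_poisson_benchmark(b)
        res = Engine(spec).run(duration)
        times, gids = res.raster
        n_post = b.n_post
        post_spikes = int((gids < n_post).sum())
        return post_spikes / n_post / (duration * 1e-3)

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate_at(mid)
        if abs(r - target_rate) <= tol:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
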
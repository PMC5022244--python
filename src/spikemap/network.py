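"""Declarative network model: populations, projections, synaptic matrices.

A :class:`NetworkSpec` is a purely declarative description of a spiking
network -- leaky integrate-and-fire populations, Poisson spike-source
populations, probabilistic projections with integer delays, optional
plasticity -- together with the simulation parameters (``dt``, duration,
seed).  :func:`build_matrices` materialises the synaptic connectivity as
row-major :class:`SynapticRow` lists, the unit in which event-driven
synapse processors fetch and process connectivity.

Connectivity is sampled from counter-based random streams keyed by
``(seed, projection, presynaptic id)`` so that the sampled pairs are a pure
function of the spec and do not depend on how the postsynaptic dimension is
later sliced across cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .plasticity import PlasticityConfig

#: Default ring-buffer depth in time steps; projection delays must fit in it.
MAX_DELAY_STEPS = 16


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NeuronParams:
    """Leaky integrate-and-fire parameters with exponential current synapses.

    ``r_membrane`` converts synaptic/injected current into the steady-state
    voltage deflection ``I * r_membrane`` (units: mV per current unit).
    ``tau_syn`` maps each receptor name (e.g. ``"exc"``, ``"inh"``) to its
    synaptic current time constant in ms.
    """

    tau_m: float = 20.0            # membrane time constant, ms
    v_rest: float = -65.0          # resting potential, mV
    v_thresh: float = -50.0        # spike threshold, mV
    v_reset: float = -65.0         # post-spike reset, mV
    t_refrac: float = 0.0          # absolute refractory period, ms
    r_membrane: float = 1.0        # input resistance, mV per current unit
    tau_syn: dict = field(default_factory=lambda: {"exc": 5.0})
    i_offset: float = 0.0          # constant bias current


@dataclass
class BackgroundInputSpec:
    """Independent Poisson background drive delivered as current input.

    Each neuron receives ``n_sources_per_neuron`` independent sources firing
    at ``rate`` Hz; every source spike injects ``weight`` onto ``receptor``.
    """

    rate: float
    n_sources_per_neuron: int
    weight: float
    receptor: str = "exc"


@dataclass
class Population:
    """A named group of identical neurons (or Poisson spike sources).

    If ``source_rate`` is set the population is a spike source: it has no
    membrane dynamics and every neuron emits independent Poisson spikes at
    that rate, routed through the network like any other spike.
    """

    name: str
    size: int
    params: Optional[NeuronParams] = None
    background: Optional[BackgroundInputSpec] = None
    source_rate: Optional[float] = None
    #: optional ("uniform", lo, hi) membrane-potential initialisation
    v_init: Optional[tuple] = None

    @property
    def is_source(self) -> bool:
        return self.source_rate is not None


@dataclass
class Stimulus:
    """A time-windowed DC current injected into a slice of a population."""

    population: str
    start_ms: float
    stop_ms: float
    current: float
    lo: int = 0
    hi: Optional[int] = None  # exclusive; None = population size


@dataclass
class Projection:
    """Connectivity between two populations.

    ``p`` is the independent per-pair connection probability; alternatively
    ``pairs`` gives an explicit (pre, post) list.  ``weight`` is either a
    scalar or ``("uniform", lo, hi)``; ``delay`` is an integer step count or
    ``("uniform_int", lo, hi)`` (inclusive bounds).  ``plasticity`` names a
    :class:`PlasticityConfig` section of the spec, or is ``None`` for static
    synapses.
    """

    pre: str
    post: str
    p: Optional[float] = None
    pairs: Optional[Sequence[tuple]] = None
    weight: object = 1.0
    delay: object = 1
    receptor: str = "exc"
    plasticity: Optional[str] = None
    allow_self: bool = False  # self-connections when pre == post


@dataclass
class SynapticRow:
    """One presynaptic neuron's synapses onto a processor's post slice.

    Plastic rows carry the header the deferred plasticity algorithm needs:
    the time of the presynaptic neuron's last spike, its low-pass-filtered
    spike trace ``s_i`` at that time, and the time the row was last updated
    (by a spike or a flush event).
    """

    pre_id: int
    post_idx: np.ndarray           # local indices within the owning slice
    delay: np.ndarray              # integer steps, >= 1
    weight: np.ndarray             # float weights (fixed-point at insert time)
    plastic: bool = False
    t_last_spike: Optional[float] = None
    s_i: float = 0.0
    t_last_update: float = 0.0

    def __len__(self) -> int:
        return len(self.post_idx)


@dataclass
class NetworkSpec:
    """Complete declarative description of a network and a run."""

    populations: list = field(default_factory=list)
    projections: list = field(default_factory=list)
    plasticity_configs: dict = field(default_factory=dict)
    dt: float = 1.0                # ms
    duration: float = 1000.0       # ms
    max_rate: float = 100.0        # Hz, network-wide bound used for flushing
    seed: int = 0
    stimuli: list = field(default_factory=list)
    max_delay: int = MAX_DELAY_STEPS

    def population(self, name: str) -> Population:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"no population named {name!r}")

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(spec: NetworkSpec) -> list[str]:
    """Check every structural invariant; return diagnostics (empty = valid).

    Diagnostics are strings naming the offending element; validation never
    raises so a caller can report all problems at once.
    """
    diags: list[str] = []
    names = [p.name for p in spec.populations]
    for name in set(names):
        if names.count(name) > 1:
            diags.append(f"population {name!r}: duplicate name")
    pops = {p.name: p for p in spec.populations}

    if spec.dt <= 0:
        diags.append(f"dt must be > 0 (got {spec.dt})")
    if spec.max_rate <= 0:
        diags.append(f"max_rate must be > 0 (got {spec.max_rate})")

    for pop in spec.populations:
        if pop.size < 1:
            diags.append(f"population {pop.name!r}: size < 1")
        if pop.is_source:
            if pop.source_rate < 0:
                diags.append(f"population {pop.name!r}: negative source rate")
            continue
        if pop.params is None:
            diags.append(f"population {pop.name!r}: neither params nor source_rate")
            continue
        pr = pop.params
        if pr.tau_m <= 0:
            diags.append(f"population {pop.name!r}: tau_m <= 0")
        if pr.v_thresh <= pr.v_reset:
            diags.append(f"population {pop.name!r}: v_thresh <= v_reset")
        if pr.t_refrac < 0:
            diags.append(f"population {pop.name!r}: t_refrac < 0")
        for rec, tau in pr.tau_syn.items():
            if tau <= 0:
                diags.append(f"population {pop.name!r}: tau_syn[{rec!r}] <= 0")
        bg = pop.background
        if bg is not None:
            if bg.rate < 0:
                diags.append(f"population {pop.name!r}: background rate < 0")
            if not np.isfinite(bg.weight):
                diags.append(f"population {pop.name!r}: background weight not finite")
            if bg.receptor not in pr.tau_syn:
                diags.append(
                    f"population {pop.name!r}: background receptor "
                    f"{bg.receptor!r} has no tau_syn")

    for i, proj in enumerate(spec.projections):
        label = f"projection[{i}] {proj.pre}->{proj.post}"
        if proj.pre not in pops:
            diags.append(f"{label}: unknown pre population")
        if proj.post not in pops:
            diags.append(f"{label}: unknown post population")
            continue
        post = pops[proj.post]
        if proj.p is None and proj.pairs is None:
            diags.append(f"{label}: needs p or explicit pairs")
        if proj.p is not None and not (0.0 <= proj.p <= 1.0):
            diags.append(f"{label}: probability {proj.p} outside [0, 1]")
        lo, hi = _delay_bounds(proj.delay)
        if lo < 1:
            diags.append(f"{label}: delay < 1 step")
        if hi > spec.max_delay:
            diags.append(
                f"{label}: delay {hi} exceeds ring-buffer depth {spec.max_delay}")
        if not post.is_source and post.params is not None:
            if proj.receptor not in post.params.tau_syn:
                diags.append(f"{label}: unknown receptor {proj.receptor!r} on post")
        if proj.plasticity is not None:
            if proj.plasticity not in spec.plasticity_configs:
                diags.append(f"{label}: unknown plasticity config "
                             f"{proj.plasticity!r}")

    for cfg_name, cfg in spec.plasticity_configs.items():
        if cfg.tau_plus <= 0 or cfg.tau_minus <= 0:
            diags.append(f"plasticity {cfg_name!r}: time constants must be > 0")
        if cfg.a_plus < 0 or cfg.a_minus < 0:
            diags.append(f"plasticity {cfg_name!r}: amplitudes must be >= 0")
        if cfg.w_max <= 0:
            diags.append(f"plasticity {cfg_name!r}: w_max must be > 0")
    return diags


def _delay_bounds(delay) -> tuple[int, int]:
    if isinstance(delay, tuple):
        _, lo, hi = delay
        return int(lo), int(hi)
    return int(delay), int(delay)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _row_rng(seed: int, proj_index: int, pre_id: int) -> np.random.Generator:
    """Counter-based stream for one synaptic row.

    Keyed by (seed, projection, pre id) so sampling a row is independent of
    every other row and of postsynaptic slicing.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(0x5B1C, proj_index, pre_id))
    return np.random.Generator(np.random.Philox(ss))


def sample_row(spec: NetworkSpec, proj_index: int, pre_id: int):
    """Sample one presynaptic neuron's full row over the whole post population.

    Returns ``(post_ids, delays, weights)`` over global post indices; the
    caller distributes entries to slices.  Deterministic in
    ``(spec.seed, proj_index, pre_id)``.
    """
    proj = spec.projections[proj_index]
    post_pop = spec.population(proj.post)
    rng = _row_rng(spec.seed, proj_index, pre_id)

    if proj.pairs is not None:
        post_ids = np.array([q for p, q in proj.pairs if p == pre_id], dtype=np.int64)
    else:
        mask = rng.random(post_pop.size) < proj.p
        if proj.pre == proj.post and not proj.allow_self:
            mask[pre_id] = False
        post_ids = np.nonzero(mask)[0]

    n = len(post_ids)
    if isinstance(proj.delay, tuple):
        _, lo, hi = proj.delay
        delays = rng.integers(int(lo), int(hi) + 1, size=n)
    else:
        delays = np.full(n, int(proj.delay), dtype=np.int64)
    if isinstance(proj.weight, tuple):
        _, lo, hi = proj.weight
        weights = rng.uniform(lo, hi, size=n)
    else:
        weights = np.full(n, float(proj.weight))
    return post_ids, delays.astype(np.int64), weights.astype(np.float64)


def build_matrices(spec: NetworkSpec, slices: Optional[dict] = None) -> dict:
    """Materialise synaptic rows for every projection, split by post slice.

    Parameters
    ----------
    spec
        Validated network description.
    slices
        Optional map from projection index to a list of ``(lo, hi)`` post
        ranges (exclusive ``hi``).  Defaults to one slice covering the whole
        postsynaptic population.

    Returns
    -------
    dict
        ``{(proj_index, (lo, hi)): [SynapticRow, ...]}`` with one row per
        presynaptic neuron that has at least one synapse in the slice.
        Row ``post_idx`` values are local to the slice (``global - lo``).

    Raises
    ------
    ValueError
        If the spec fails :func:`validate`.
    """
    diags = validate(spec)
    if diags:
        raise ValueError("invalid network spec:\n  " + "\n  ".join(diags))

    out: dict = {}
    for pi, proj in enumerate(spec.projections):
        pre_pop = spec.population(proj.pre)
        post_pop = spec.population(proj.post)
        proj_slices = (slices or {}).get(pi, [(0, post_pop.size)])
        plastic = proj.plasticity is not None
        for sl in proj_slices:
            out[(pi, tuple(sl))] = []
        for pre_id in range(pre_pop.size):
            post_ids, delays, weights = sample_row(spec, pi, pre_id)
            if len(post_ids) == 0:
                continue
            for lo, hi in proj_slices:
                sel = (post_ids >= lo) & (post_ids < hi)
                if not sel.any():
                    continue
                out[(pi, (lo, hi))].append(SynapticRow(
                    pre_id=pre_id,
                    post_idx=(post_ids[sel] - lo).astype(np.int64),
                    delay=delays[sel],
                    weight=weights[sel].copy(),
                    plastic=plastic,
                ))
    return out
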
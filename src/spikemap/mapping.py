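"""Cycle-cost models and network-to-core partitioning.

Models the per-time-step CPU budget of 200 MHz many-core hardware in which
each core must finish its share of the network within ``clock * dt`` clock
cycles to keep up with real time.  Two mappings are provided:

* **standard**: each core simulates a slice of neurons *and* their entire
  afferent synaptic column block; the neuron count per core follows from
  the per-neuron and per-synaptic-event cycle costs.
* **synapse-centric**: dedicated *synapse processors* hold the synaptic
  matrix row-wise, split (a) by synapse type / plasticity rule, (b)
  postsynaptically by ring-buffer / history memory limits (1024 static,
  512 plastic postsynaptic neurons), and (c) presynaptically by processing
  cost; *neuron processors* sum the per-step input buffers and integrate
  the membrane dynamics; *current-input processors* deliver Poisson
  background as pre-weighted current vectors.

The row-aware cost of a synapse processor is
``events/s * per_event + rows/s * per_row`` cycles per second: the per-row
term is the fixed overhead (DMA setup, interrupt servicing, loop setup)
amortised over ever-shorter rows as connectivity gets sparser, which is
what makes sparse cortical connectivity expensive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

from .network import NetworkSpec, Population


# ---------------------------------------------------------------------------
# Cost constants
# ---------------------------------------------------------------------------

@dataclass
class CostConstants:
    """Profiled cycle costs and capacity limits of the target hardware.

    Per-event costs of plastic synapses depend on ``h``, the expected
    number of postsynaptic history entries replayed per row visit.  The
    per-row overheads of the synapse-centric processors are not directly
    profiled figures; the defaults are calibrated to the admissible range
    implied by the measured processor counts and are configurable.
    """

    clock_hz: float = 200e6
    # standard mapping
    std_per_neuron: float = 181.0          # cycles per neuron per step, static
    std_per_event: float = 21.0            # cycles per static synaptic event
    std_stdp_per_neuron: float = 187.0     # cycles per neuron per step, plastic
    std_stdp_event_base: float = 131.0     # plastic event cost = base + slope*h
    std_stdp_event_slope: float = 31.0
    std_neuron_cap: int = 256              # practical static neurons per core
    # synapse-centric mapping
    sc_static_per_event: float = 15.0
    sc_stdp_event_base: float = 107.0
    sc_stdp_event_slope: float = 30.0
    sc_static_per_row: float = 800.0       # fixed cost per row visit, cycles
    sc_stdp_per_row: float = 1500.0
    neuron_proc_cap: int = 1024            # LIF neurons one neuron core handles
    static_post_limit: int = 1024          # ring-buffer memory limit
    stdp_post_limit: int = 512             # + post-history memory limit
    chip_cores: int = 16                   # cores sharing one buffer group

    def per_event(self, kind: str, h: float = 1.0, standard: bool = False) -> float:
        if kind == "static":
            return self.std_per_event if standard else self.sc_static_per_event
        if kind == "stdp":
            if standard:
                return self.std_stdp_event_base + self.std_stdp_event_slope * h
            return self.sc_stdp_event_base + self.sc_stdp_event_slope * h
        raise ValueError(f"unknown synapse kind {kind!r}")

    def per_row(self, kind: str) -> float:
        return self.sc_static_per_row if kind == "static" else self.sc_stdp_per_row

    def post_limit(self, kind: str) -> int:
        return self.static_post_limit if kind == "static" else self.stdp_post_limit


@dataclass
class RateAssumptions:
    """Planning-time activity assumptions.

    ``mean_rate_hz`` is the expected presynaptic firing rate (the 3 Hz
    cortical assumption behind the 8000-input, 24 kHz per-neuron figure);
    ``h`` the expected history entries replayed per plastic row visit
    (1 when pre and post fire at similar rates).  Per-population overrides
    by name.
    """

    mean_rate_hz: float = 3.0
    h: float = 1.0
    per_population: dict = field(default_factory=dict)

    def rate(self, population: str) -> float:
        return self.per_population.get(population, self.mean_rate_hz)


class InfeasiblePartitionError(ValueError):
    """A single indivisible unit of work exceeds one core's budget."""


# ---------------------------------------------------------------------------
# Closed-form estimators
# ---------------------------------------------------------------------------

def estimate_standard_neurons_per_core(
        dt: float, mu_input: float, plastic: bool = False, h: float = 1.0,
        costs: Optional[CostConstants] = None) -> int:
    """Neurons one standard-mapping core can simulate in real time.

    ``floor(clock / (per_neuron/dt + per_event(h) * mu_input))`` with dt in
    ms and ``mu_input`` in synaptic events per neuron per second; the static
    estimate is additionally capped at the practical 256-neuron limit.
    """
    if dt <= 0 or mu_input < 0:
        raise ValueError("dt must be > 0 and mu_input >= 0")
    c = costs or CostConstants()
    per_neuron = c.std_stdp_per_neuron if plastic else c.std_per_neuron
    kind = "stdp" if plastic else "static"
    per_event = c.per_event(kind, h, standard=True)
    denom = per_neuron / (dt * 1e-3) + per_event * mu_input
    n = math.floor(c.clock_hz / denom)
    if not plastic:
        n = min(n, c.std_neuron_cap)
    return n


def synproc_capacity(row_len: float, kind: str, h: float = 1.0,
                     costs: Optional[CostConstants] = None,
                     per_row: Optional[float] = None) -> float:
    """Synaptic events/s one synapse processor sustains at mean row length.

    ``clock / (per_event + per_row/row_len)``; with ``per_row = 0`` this is
    the peak (long-row limit) throughput.
    """
    if row_len < 1:
        raise ValueError("row_len must be >= 1")
    c = costs or CostConstants()
    if per_row is None:
        per_row = c.per_row(kind)
    return c.clock_hz / (c.per_event(kind, h) + per_row / row_len)


def count_synapse_processors(
        n_post: int, per_neuron_input: float, rows_per_s: float,
        row_len: float, kind: str = "static", h: float = 1.0,
        costs: Optional[CostConstants] = None,
        per_row: Optional[float] = None,
        step_budget_cycles: Optional[float] = None) -> int:
    """Minimal synapse-processor count for one postsynaptic group.

    Events and row fetches divide evenly across ``k`` processors, so the
    minimal feasible count is the ceiling of total cycle demand over one
    core's cycle supply.  ``per_row=0`` gives the peak-throughput estimate
    that ignores row overhead.  If ``step_budget_cycles`` is given, a
    single row visit must fit within one time step's budget, otherwise the
    row is indivisible and the partition infeasible.
    """
    if n_post < 1 or per_neuron_input < 0 or rows_per_s < 0:
        raise ValueError("arguments must be positive")
    c = costs or CostConstants()
    if per_row is None:
        per_row = c.per_row(kind)
    if step_budget_cycles is not None and row_len >= 1:
        row_cost = row_len * c.per_event(kind, h) + per_row
        if row_cost > step_budget_cycles:
            raise InfeasiblePartitionError(
                f"one row of {row_len:.0f} {kind} synapses costs "
                f"{row_cost:.0f} cycles, over the {step_budget_cycles:.0f}"
                " cycle step budget")
    total = n_post * per_neuron_input * c.per_event(kind, h) + rows_per_s * per_row
    return max(1, math.ceil(total / c.clock_hz))


# ---------------------------------------------------------------------------
# Core allocation
# ---------------------------------------------------------------------------

@dataclass
class VirtualCore:
    """One virtual processor in an allocation.

    ``role`` is ``neuron`` (membrane dynamics; for the standard mapping the
    same core also processes its afferent synapses), ``synapse`` (row-wise
    event-driven synapse processing) or ``current_input`` (background
    Poisson converted to current vectors).  ``slice`` is the half-open
    postsynaptic (or neuron) range within ``population``.  Synapse cores
    additionally carry the synapse kind, receptor, plasticity tag, and the
    presynaptic sources they subscribe to as
    ``[(projection_index, pre_lo, pre_hi), ...]``.
    """

    role: str
    population: str
    slice: tuple
    kind: Optional[str] = None
    receptor: Optional[str] = None
    plasticity: Optional[str] = None
    sources: list = field(default_factory=list)
    est_cycles_per_step: float = 0.0


@dataclass
class CoreAllocation:
    """A complete mapping of a network onto virtual cores."""

    scheme: str                     # "standard" | "synapse_centric"
    cores: list = field(default_factory=list)
    dt: float = 1.0

    def by_role(self, role: str) -> list:
        return [c for c in self.cores if c.role == role]

    @property
    def n_neuron_cores(self) -> int:
        return len(self.by_role("neuron"))

    @property
    def n_synapse_cores(self) -> int:
        return len(self.by_role("synapse"))

    @property
    def n_current_input_cores(self) -> int:
        return len(self.by_role("current_input"))

    @property
    def total_cores(self) -> int:
        return len(self.cores)

    @property
    def step_budget_cycles(self) -> float:
        return CostConstants().clock_hz * self.dt * 1e-3

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "neuron_cores": self.n_neuron_cores,
            "synapse_cores": self.n_synapse_cores,
            "current_input_cores": self.n_current_input_cores,
            "total_cores": self.total_cores,
        }

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "dt": self.dt,
            "summary": self.summary(),
            "cores": [asdict(c) for c in self.cores],
        }


# -- helpers ----------------------------------------------------------------

def _afferent_types(spec: NetworkSpec, pop: Population) -> dict:
    """Group afferent projections of ``pop`` by (kind, receptor, plasticity)."""
    types: dict = {}
    for pi, proj in enumerate(spec.projections):
        if proj.post != pop.name:
            continue
        kind = "stdp" if proj.plasticity is not None else "static"
        key = (kind, proj.receptor, proj.plasticity)
        types.setdefault(key, []).append(pi)
    return types


def _type_load(spec: NetworkSpec, proj_indices: list, rates: RateAssumptions,
               chunk: int):
    """(events/s, rows/s, mean row length) for one type onto ``chunk`` posts."""
    rows_per_s = 0.0
    events_per_s = 0.0
    for pi in proj_indices:
        proj = spec.projections[pi]
        pre = spec.population(proj.pre)
        rate = pre.source_rate if pre.is_source else rates.rate(proj.pre)
        p = proj.p if proj.p is not None else (
            len(proj.pairs) / (pre.size * spec.population(proj.post).size))
        rows_per_s += pre.size * rate
        events_per_s += pre.size * rate * p * chunk
    row_len = events_per_s / rows_per_s if rows_per_s > 0 else 1.0
    return events_per_s, rows_per_s, max(row_len, 1e-9)


def _split_range(lo: int, hi: int, n: int) -> list:
    """Split [lo, hi) into n near-equal contiguous parts (may drop empties)."""
    edges = [lo + round(i * (hi - lo) / n) for i in range(n + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n)
            if edges[i + 1] > edges[i]]


def _largest_remainder(ideals: list[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``ideals``."""
    floors = [math.floor(x) for x in ideals]
    rem = total - sum(floors)
    order = sorted(range(len(ideals)), key=lambda i: ideals[i] - floors[i],
                   reverse=True)
    for i in order[:rem]:
        floors[i] += 1
    return floors


# ---------------------------------------------------------------------------
# Partitioners
# ---------------------------------------------------------------------------

def partition_synapse_centric(
        spec: NetworkSpec, rates: Optional[RateAssumptions] = None,
        costs: Optional[CostConstants] = None,
        force_presyn_split: Optional[dict] = None) -> CoreAllocation:
    """Allocate neuron / synapse / current-input cores, synapse-centrically.

    Per population the afferent synapses are split first by synapse type
    (receptor x plasticity rule), then postsynaptically at the 1024-static /
    512-plastic memory limits, then presynaptically by the row-aware cost
    model.  Neuron processors hold 1024 neurons, halved to 512 when a
    1024-neuron group needs >= 4 synapse processors or a shared-buffer group
    would exceed the 16 cores of one chip.  One current-input core per
    neuron core serves populations with Poisson background.

    ``force_presyn_split`` maps population name -> presynaptic split count,
    overriding the cost model (used to exercise partition invariance).
    """
    rates = rates or RateAssumptions()
    costs = costs or CostConstants()
    budget = costs.clock_hz * spec.dt * 1e-3
    alloc = CoreAllocation(scheme="synapse_centric", dt=spec.dt)

    for pop in spec.populations:
        if pop.size < 1:
            raise ValueError(f"population {pop.name!r} is empty")
        if pop.is_source:
            # Spike sources only emit; pack them like neuron processors.
            for lo, hi in _chunks(pop.size, costs.neuron_proc_cap):
                alloc.cores.append(VirtualCore(
                    role="neuron", population=pop.name, slice=(lo, hi),
                    est_cycles_per_step=0.0))
            continue

        types = _afferent_types(spec, pop)
        forced = (force_presyn_split or {}).get(pop.name)

        # Per-type processor count for one full 1024-post window, and its
        # contribution to k_group (plastic types need 2 cores per window
        # because of the 512-post history limit).
        k_chunk: dict = {}
        k_scaled: dict = {}
        for key, pis in types.items():
            kind = key[0]
            limit = costs.post_limit(kind)
            chunk = min(limit, pop.size)
            ev, rows, rlen = _type_load(spec, pis, rates, chunk)
            if forced is not None:
                k = forced
            else:
                k = count_synapse_processors(
                    chunk, ev / chunk if chunk else 0.0, rows, rlen, kind,
                    rates.h, costs, step_budget_cycles=budget)
            k_chunk[key] = k
            window = min(1024, pop.size)
            k_scaled[key] = k * max(1, math.ceil(window / chunk) if chunk < window else 1)
        k_group = sum(k_scaled.values()) if types else 0

        size = costs.neuron_proc_cap
        if k_group >= 4 or (1 + k_group) > costs.chip_cores:
            size //= 2
        n_neuron_cores = math.ceil(pop.size / size)

        # Neuron cores.
        for lo, hi in _chunks(pop.size, size):
            alloc.cores.append(VirtualCore(
                role="neuron", population=pop.name, slice=(lo, hi),
                est_cycles_per_step=(hi - lo) * costs.std_per_neuron))

        # Synapse cores: population total follows the neuron-core-aligned
        # count, apportioned over types, then spread over post chunks.
        if types:
            scale = size / 1024.0
            total_syn = math.ceil(n_neuron_cores * k_group * scale)
            keys = list(types)
            per_type = _largest_remainder(
                [n_neuron_cores * k_scaled[k] * scale for k in keys], total_syn)
            for key, n_type in zip(keys, per_type):
                kind, receptor, plast = key
                limit = costs.post_limit(kind)
                chunks = _chunks(pop.size, limit)
                # The neuron-core-aligned total can come up one short of the
                # chunk count when the population leaves a partial trailing
                # window; absorb that partial chunk into its predecessor
                # (the memory margin of a short window covers it).
                while n_type < len(chunks) and len(chunks) > 1:
                    last = chunks.pop()
                    chunks[-1] = (chunks[-1][0], last[1])
                n_type = max(n_type, len(chunks))
                base, extra = divmod(n_type, len(chunks))
                for ci, (lo, hi) in enumerate(chunks):
                    k_here = base + (1 if ci < extra else 0)
                    _emit_synapse_cores(
                        alloc, spec, pop, key, types[key], (lo, hi), k_here,
                        rates, costs)
        # Current-input cores.
        if pop.background is not None:
            for lo, hi in _chunks(pop.size, size):
                bg = pop.background
                ev = (hi - lo) * bg.n_sources_per_neuron * bg.rate
                alloc.cores.append(VirtualCore(
                    role="current_input", population=pop.name, slice=(lo, hi),
                    receptor=bg.receptor,
                    est_cycles_per_step=ev * spec.dt * 1e-3))
    return alloc


def _chunks(size: int, chunk: int) -> list:
    return [(lo, min(lo + chunk, size)) for lo in range(0, size, chunk)]


def _emit_synapse_cores(alloc, spec, pop, key, proj_indices, post_slice,
                        k, rates, costs):
    """Emit ``k`` synapse cores for one (type, post chunk), splitting presyn."""
    kind, receptor, plast = key
    lo, hi = post_slice
    # Concatenate the presynaptic index space of all projections of the type.
    spans = []
    for pi in proj_indices:
        pre = spec.population(spec.projections[pi].pre)
        spans.append((pi, pre.size))
    total_pre = sum(s for _, s in spans)
    cuts = _split_range(0, total_pre, max(1, k))
    ev_full, rows_full, rlen = _type_load(spec, proj_indices, rates, hi - lo)
    for (clo, chi) in cuts:
        sources = []
        off = 0
        for pi, size in spans:
            s_lo = max(clo - off, 0)
            s_hi = min(chi - off, size)
            if s_hi > s_lo:
                sources.append((pi, s_lo, s_hi))
            off += size
        frac = (chi - clo) / total_pre if total_pre else 1.0
        est = (ev_full * costs.per_event(kind, rates.h)
               + rows_full * costs.per_row(kind)) * frac * spec.dt * 1e-3
        alloc.cores.append(VirtualCore(
            role="synapse", population=pop.name, slice=(lo, hi), kind=kind,
            receptor=receptor, plasticity=plast, sources=sources,
            est_cycles_per_step=est))


def partition_standard(spec: NetworkSpec,
                       rates: Optional[RateAssumptions] = None,
                       costs: Optional[CostConstants] = None) -> CoreAllocation:
    """Column-wise mapping: each core owns a neuron slice plus its synapses.

    The slice size comes from the standard cost model with the population's
    expected per-neuron input rate; afferent rows for a slice live with the
    slice, so every presynaptic spike is processed once per subscribing
    core.
    """
    rates = rates or RateAssumptions()
    costs = costs or CostConstants()
    alloc = CoreAllocation(scheme="standard", dt=spec.dt)
    for pop in spec.populations:
        if pop.is_source:
            for lo, hi in _chunks(pop.size, costs.neuron_proc_cap):
                alloc.cores.append(VirtualCore(
                    role="neuron", population=pop.name, slice=(lo, hi)))
            continue
        mu = 0.0
        plastic = False
        for pi, proj in enumerate(spec.projections):
            if proj.post != pop.name:
                continue
            pre = spec.population(proj.pre)
            rate = pre.source_rate if pre.is_source else rates.rate(proj.pre)
            p = proj.p if proj.p is not None else 1.0
            mu += pre.size * rate * p
            plastic = plastic or proj.plasticity is not None
        if pop.background is not None:
            mu += pop.background.n_sources_per_neuron * pop.background.rate
        n = estimate_standard_neurons_per_core(
            spec.dt, mu, plastic=plastic, h=rates.h, costs=costs)
        n = max(1, n)
        per_neuron = costs.std_stdp_per_neuron if plastic else costs.std_per_neuron
        per_event = costs.per_event("stdp" if plastic else "static",
                                    rates.h, standard=True)
        for lo, hi in _chunks(pop.size, n):
            # cycles/step: neuron updates + expected events into this slice
            est = ((hi - lo) * per_neuron
                   + per_event * mu * (hi - lo) * spec.dt * 1e-3)
            alloc.cores.append(VirtualCore(
                role="neuron", population=pop.name, slice=(lo, hi),
                est_cycles_per_step=est))
    return alloc


# ---------------------------------------------------------------------------
# Feasibility audit
# ---------------------------------------------------------------------------

def audit_allocation(alloc: CoreAllocation, recorded_activity: dict,
                     costs: Optional[CostConstants] = None,
                     h: float = 1.0) -> dict:
    """Check real-time feasibility of an allocation against a recorded run.

    ``recorded_activity`` maps core index -> ``{"events": array,
    "rows": array}`` of per-step counts (as produced by the engine).  The
    report gives, per core, the worst-step measured cycle cost, the step
    budget ``clock * dt``, the headroom fraction, and whether any step
    overran.
    """
    costs = costs or CostConstants()
    budget = costs.clock_hz * alloc.dt * 1e-3
    report = {"budget_cycles_per_step": budget, "cores": [], "overruns": 0}
    for idx, core in enumerate(alloc.cores):
        act = recorded_activity.get(idx)
        n = core.slice[1] - core.slice[0]
        if core.role == "synapse":
            per_event = costs.per_event(core.kind, h)
            per_row = costs.per_row(core.kind)
            if act is None:
                worst = mean = 0.0
            else:
                cyc = act["events"] * per_event + act["rows"] * per_row
                worst = float(cyc.max()) if len(cyc) else 0.0
                mean = float(cyc.mean()) if len(cyc) else 0.0
        elif core.role == "current_input":
            per_event = costs.sc_static_per_event
            if act is None:
                worst = mean = 0.0
            else:
                cyc = act["events"] * per_event
                worst = float(cyc.max()) if len(cyc) else 0.0
                mean = float(cyc.mean()) if len(cyc) else 0.0
        else:  # neuron (standard cores include their synaptic events)
            base = n * costs.std_per_neuron
            if act is not None and len(act.get("events", [])):
                per_event = costs.per_event(
                    act.get("kind", "static"), h, standard=True)
                cyc = base + act["events"] * per_event
                worst = float(cyc.max())
                mean = float(cyc.mean())
            else:
                worst = mean = float(base)
        over = worst > budget
        report["cores"].append({
            "core": idx, "role": core.role, "population": core.population,
            "slice": list(core.slice), "worst_cycles": worst,
            "mean_cycles": mean, "headroom": 1.0 - worst / budget,
            "overrun": bool(over),
        })
        if over:
            report["overruns"] += 1
    busiest = max(report["cores"], key=lambda c: c["worst_cycles"],
                  default=None)
    report["busiest_core"] = busiest["core"] if busiest else None
    return report
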
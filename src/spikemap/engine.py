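"""Step-wise execution of a partitioned network as communicating virtual cores.

Each simulation step runs three phases, mirroring the shared-buffer
dataflow of the hardware:

1. *Synapse cores* process every spike/flush event routed in the previous
   step -- static rows are accumulated straight into the core's fixed-point
   ring buffer; plastic rows run the deferred plasticity replay -- then
   drain the ring slot for the current step and publish the result as an
   input buffer.  *Current-input cores* publish their Poisson background
   vectors.
2. *Neuron cores* sum their input buffers per receptor (still in integer
   fixed point, so the sum is independent of how buffers were split),
   integrate the membrane dynamics, and emit spike keys; silent neurons
   past the flush threshold emit flush keys.
3. The router enqueues the emitted keys for the next step's processing.

A spike emitted with timestamp ``t`` and projection delay ``d`` affects the
postsynaptic membrane at exactly ``t + d*dt``: routing consumes one step
and the ring buffer the remaining ``d - 1``.  Event processing within a
core is ordered by key, replacing hardware arrival nondeterminism with a
deterministic convention; together with fixed-point accumulation this
makes rasters and final weights bit-identical across partitionings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import plasticity as plast
from .mapping import CoreAllocation, partition_synapse_centric
from .network import NetworkSpec, SynapticRow, sample_row, validate
from .plasticity import FlushPolicy, PostHistory, process_row
from .simcore import (DEFAULT_FRACTION_BITS, LifDecay, NeuronState,
                      RingBuffer, lif_step, poisson_spike_prob, step_rng)

# Stream domains for counter-based RNG (keyed with population index).
_DOMAIN_SOURCE = 0
_DOMAIN_BACKGROUND = 1
_DOMAIN_VINIT = 2


@dataclass
class RoutingKey:
    """A multicast event: 31-bit global neuron id plus the flush bit."""

    neuron_id: int
    flush: bool = False

    def sort_key(self):
        return (self.neuron_id, self.flush)


class _RingAdapter:
    """Presents projection-delay ``insert`` over engine drain offsets.

    The routing fabric already consumed one step of the delay, so a
    projection delay ``d`` becomes ring offset ``d - 1`` (0 = drained in
    the current step's drain, which happens after all inserts).
    """

    __slots__ = ("ring",)

    def __init__(self, ring: RingBuffer):
        self.ring = ring

    def insert(self, neuron: int, delay: int, weight: float) -> None:
        self.ring.insert_offset([neuron], [delay - 1],
                                self.ring.to_fixed(weight))


class _SynapseUnit:
    """One synapse processor: a (type, post slice, presyn span) of rows."""

    def __init__(self, core_index, pop_name, post_slice, kind, receptor,
                 plasticity_name, ring_depth, history_capacity):
        self.core_index = core_index
        self.pop_name = pop_name
        self.lo, self.hi = post_slice
        self.kind = kind
        self.receptor = receptor
        self.plasticity_name = plasticity_name
        self.ring = RingBuffer(self.hi - self.lo, depth=ring_depth)
        self.adapter = _RingAdapter(self.ring)
        # static storage (CSR over arrival order)
        self._post = []
        self._off = []
        self._wfix = []
        self.static_index: dict = {}     # gid -> [(start, end), ...]
        self.post_arr = self.off_arr = self.wfix_arr = None
        # plastic storage
        self.cfg = None                  # PlasticityConfig for stdp units
        self.rows: dict = {}             # gid -> SynapticRow
        self.histories = ([PostHistory(history_capacity)
                           for _ in range(self.hi - self.lo)]
                          if kind == "stdp" else None)
        # audit counters for the current step
        self.step_events = 0
        self.step_rows = 0

    def add_static(self, gid, post_local, delays, weights_fixed):
        start = sum(len(p) for p in self._post)
        self._post.append(post_local)
        self._off.append(delays - 1)
        self._wfix.append(weights_fixed)
        self.static_index.setdefault(gid, []).append(
            (start, start + len(post_local)))

    def finalize(self):
        if self._post:
            self.post_arr = np.concatenate(self._post)
            self.off_arr = np.concatenate(self._off)
            self.wfix_arr = np.concatenate(self._wfix)
        self._post = self._off = self._wfix = None


class RunResult:
    """Raster, weights, and per-core audit statistics of one run."""

    def __init__(self, n_cores, n_steps):
        self.spike_times: list = []
        self.spike_gids: list = []
        self.events = np.zeros((n_cores, n_steps))
        self.rows = np.zeros((n_cores, n_steps))
        self.flush_count = 0
        self.lost_entries = 0
        self.weights: dict = {}
        self.v_trace: Optional[np.ndarray] = None

    @property
    def raster(self):
        return (np.asarray(self.spike_times),
                np.asarray(self.spike_gids, dtype=np.int64))

    def activity(self) -> dict:
        return {i: {"events": self.events[i], "rows": self.rows[i]}
                for i in range(self.events.shape[0])}


class Engine:
    """Executable instance of (network spec, core allocation)."""

    def __init__(self, spec: NetworkSpec, alloc: Optional[CoreAllocation] = None,
                 history_capacity: Optional[int] = plast.DEFAULT_HISTORY_CAPACITY,
                 enable_flush: bool = True):
        diags = validate(spec)
        if diags:
            raise ValueError("invalid network spec:\n  " + "\n  ".join(diags))
        self.spec = spec
        self.alloc = alloc if alloc is not None else partition_synapse_centric(spec)
        self.enable_flush = enable_flush
        self.history_capacity = history_capacity
        self.dt = spec.dt
        self.step_index = 0
        self.pending: list = []          # events emitted last step

        # -- population bookkeeping ----------------------------------------
        self.pops = {p.name: p for p in spec.populations}
        self.offsets: dict = {}
        off = 0
        for p in spec.populations:
            self.offsets[p.name] = off
            off += p.size
        self.pop_index = {p.name: i for i, p in enumerate(spec.populations)}
        self.states: dict = {}
        self.decays: dict = {}
        for p in spec.populations:
            if p.is_source:
                continue
            v0 = self._initial_v(p)
            self.states[p.name] = NeuronState.create(p.size, p.params, v0)
            self.decays[p.name] = LifDecay.create(p.params, spec.dt)
        # integer input accumulators, reset each step
        self.scale = float(1 << DEFAULT_FRACTION_BITS)

        # -- flush policy ----------------------------------------------------
        self.policy = FlushPolicy(
            max_rate=spec.max_rate,
            buffer_size=history_capacity or plast.DEFAULT_HISTORY_CAPACITY)
        plastic_pre = {spec.projections[pi].pre for pi in
                       range(len(spec.projections))
                       if spec.projections[pi].plasticity is not None}
        self.flush_pops = plastic_pre if enable_flush else set()
        self.last_event: dict = {
            name: np.zeros(self.pops[name].size) for name in plastic_pre}

        # -- build synapse processing units ---------------------------------
        self.units: list = []
        self._build_units()

    # ------------------------------------------------------------------ init
    def _initial_v(self, pop):
        init = getattr(pop, "v_init", None)
        if init is None:
            return None
        _, lo, hi = init
        rng = step_rng(self.spec.seed,
                       _DOMAIN_VINIT * 1000 + self.pop_index[pop.name], 0)
        return rng.uniform(lo, hi, size=pop.size)

    def _build_units(self):
        spec = self.spec
        if self.alloc.scheme == "synapse_centric":
            unit_specs = [
                (ci, core.population, core.slice, core.kind, core.receptor,
                 core.plasticity, core.sources)
                for ci, core in enumerate(self.alloc.cores)
                if core.role == "synapse"]
        else:
            # Standard mapping: each neuron core owns its slice's afferent
            # column block, one internal unit per synapse type.
            unit_specs = []
            for ci, core in enumerate(self.alloc.cores):
                if core.role != "neuron":
                    continue
                pop = self.pops[core.population]
                if pop.is_source:
                    continue
                types: dict = {}
                for pi, proj in enumerate(spec.projections):
                    if proj.post != core.population:
                        continue
                    kind = "stdp" if proj.plasticity is not None else "static"
                    key = (kind, proj.receptor, proj.plasticity)
                    types.setdefault(key, []).append(pi)
                for (kind, receptor, pl), pis in types.items():
                    sources = [(pi, 0, self.pops[spec.projections[pi].pre].size)
                               for pi in pis]
                    unit_specs.append((ci, core.population, core.slice, kind,
                                       receptor, pl, sources))

        by_proj: dict = {}
        for us in unit_specs:
            ci, pop_name, sl, kind, receptor, pl, sources = us
            unit = _SynapseUnit(ci, pop_name, sl, kind, receptor, pl,
                                spec.max_delay, self.history_capacity)
            self.units.append(unit)
            for (pi, plo, phi) in sources:
                by_proj.setdefault(pi, []).append((unit, plo, phi))

        # Sample each row once and distribute entries to subscribing units.
        self.subscribers: dict = {}      # gid -> [(unit, row-or-None), ...]
        for pi, subs in by_proj.items():
            proj = spec.projections[pi]
            pre_pop = self.pops[proj.pre]
            pre_off = self.offsets[proj.pre]
            plastic = proj.plasticity is not None
            cfg = spec.plasticity_configs.get(proj.plasticity)
            for pre_id in range(pre_pop.size):
                gid = pre_off + pre_id
                post_ids, delays, weights = sample_row(spec, pi, pre_id)
                if len(post_ids) == 0:
                    continue
                for unit, plo, phi in subs:
                    if not (plo <= pre_id < phi):
                        continue
                    sel = (post_ids >= unit.lo) & (post_ids < unit.hi)
                    if not sel.any():
                        continue
                    local = (post_ids[sel] - unit.lo).astype(np.int64)
                    if plastic:
                        row = SynapticRow(
                            pre_id=gid, post_idx=local, delay=delays[sel],
                            weight=weights[sel].copy(), plastic=True)
                        unit.rows[gid] = (row, cfg, pi)
                        unit.cfg = cfg
                        self.subscribers.setdefault(gid, []).append(unit)
                    else:
                        wfix = np.rint(weights[sel] * self.scale).astype(np.int64)
                        unit.add_static(gid, local, delays[sel], wfix)
                        self.subscribers.setdefault(gid, []).append(unit)
        for unit in self.units:
            unit.finalize()

        # Units grouped by post population for history updates and drains.
        self.units_by_pop: dict = {}
        for unit in self.units:
            self.units_by_pop.setdefault(unit.pop_name, []).append(unit)

    # ------------------------------------------------------------------ step
    def step(self, result: Optional[RunResult] = None):
        """Advance one time step; return the events emitted at its end."""
        k = self.step_index
        t_now = (k + 1) * self.dt        # timestamp of events emitted now
        t_proc = k * self.dt             # timestamp of events being processed
        spec = self.spec

        for unit in self.units:
            unit.step_events = 0
            unit.step_rows = 0

        # Phase 1a: post-history updates (plastic units observe post spikes).
        events = sorted(self.pending, key=RoutingKey.sort_key)
        for unit in self.units:
            if unit.kind != "stdp":
                continue
            if events and unit.rows:
                # Everything at or before the slowest row's last update has
                # been replayed everywhere; only younger overwrites count
                # as genuinely lost history.
                wm = min(r[0].t_last_update for r in unit.rows.values())
                for h in unit.histories:
                    h.mark_consumed(wm)
            pop_off = self.offsets[unit.pop_name]
            for ev in events:
                if ev.flush:
                    continue
                local = ev.neuron_id - pop_off - unit.lo
                if 0 <= local < (unit.hi - unit.lo):
                    cfg = unit.cfg or plast.PlasticityConfig()
                    unit.histories[local].add_post_spike(t_proc, cfg)

        # Phase 1b: row processing.
        for ev in events:
            for unit in self.subscribers.get(ev.neuron_id, ()):
                if unit.kind == "static":
                    if ev.flush:
                        continue
                    spans = unit.static_index.get(ev.neuron_id)
                    if spans is None:
                        continue
                    for s, e in spans:
                        unit.ring.insert_offset(unit.post_arr[s:e],
                                                unit.off_arr[s:e],
                                                unit.wfix_arr[s:e])
                        unit.step_events += e - s
                        unit.step_rows += 1
                else:
                    entry = unit.rows.get(ev.neuron_id)
                    if entry is None:
                        continue
                    row, cfg, _pi = entry
                    process_row(t_proc, ev.flush, row, unit.histories,
                                unit.adapter, cfg)
                    unit.step_events += len(row)
                    unit.step_rows += 1

        # Phase 1c: drain ring buffers into per-population integer buffers.
        acc: dict = {}
        for pop_name, units in self.units_by_pop.items():
            pop = self.pops[pop_name]
            for unit in units:
                drained = unit.ring.drain_fixed()
                key = (pop_name, unit.receptor)
                if key not in acc:
                    acc[key] = np.zeros(pop.size, dtype=np.int64)
                acc[key][unit.lo:unit.hi] += drained

        # Phase 1d: current-input cores publish background vectors.
        ci_events = self._background_input(k, acc, result)

        # Phase 2: neuron cores integrate and emit.
        emitted: list = []
        for pop in spec.populations:
            if pop.is_source:
                p_spike = poisson_spike_prob(pop.source_rate, self.dt)
                rng = step_rng(spec.seed,
                               _DOMAIN_SOURCE * 1000 + self.pop_index[pop.name], k)
                mask = rng.random(pop.size) < p_spike
                spiking = np.nonzero(mask)[0]
            else:
                state = self.states[pop.name]
                drained = {}
                for rec in pop.params.tau_syn:
                    a = acc.get((pop.name, rec))
                    drained[rec] = (a / self.scale) if a is not None else None
                drained = {r: v for r, v in drained.items() if v is not None}
                i_extra = self._stimulus_current(pop, t_now)
                mask = lif_step(state, drained, pop.params, self.dt,
                                self.decays[pop.name], i_extra)
                spiking = np.nonzero(mask)[0]
                state.t_last_own_spike[spiking] = t_now
            off = self.offsets[pop.name]
            for idx in spiking:
                emitted.append(RoutingKey(off + int(idx), False))
            if result is not None:
                result.spike_times.extend([t_now] * len(spiking))
                result.spike_gids.extend((off + spiking).tolist())

            # Flush emission for presynaptic populations of plastic rows.
            if pop.name in self.flush_pops:
                last = self.last_event[pop.name]
                last[spiking] = t_now
                due = np.nonzero(t_now - last >= self.policy.threshold_ms)[0]
                for idx in due:
                    emitted.append(RoutingKey(off + int(idx), True))
                last[due] = t_now
                if result is not None:
                    result.flush_count += len(due)

        # Phase 3: router enqueues for the next step.
        self.pending = emitted
        if result is not None:
            for unit in self.units:
                result.events[unit.core_index, k] += unit.step_events
                result.rows[unit.core_index, k] += unit.step_rows
            for ci, n_ev in ci_events:
                result.events[ci, k] += n_ev
        self.step_index += 1
        return emitted

    def _background_input(self, k, acc, result):
        """Generate Poisson background as weighted current vectors.

        Draws come from a counter-based stream keyed by (seed, population,
        step), so the realised input never depends on core grouping; the
        per-core event counts are attributed to the allocation's
        current-input cores for auditing.
        """
        ci_events = []
        for pop in self.spec.populations:
            bg = pop.background
            if bg is None or pop.is_source:
                continue
            p_one = poisson_spike_prob(bg.rate, self.dt)
            rng = step_rng(self.spec.seed,
                           _DOMAIN_BACKGROUND * 1000 + self.pop_index[pop.name], k)
            counts = rng.binomial(bg.n_sources_per_neuron, p_one, size=pop.size)
            wfix = int(round(bg.weight * self.scale))
            key = (pop.name, bg.receptor)
            if key not in acc:
                acc[key] = np.zeros(pop.size, dtype=np.int64)
            acc[key] += counts.astype(np.int64) * wfix
            if result is not None:
                for ci, core in enumerate(self.alloc.cores):
                    if core.role == "current_input" and core.population == pop.name:
                        lo, hi = core.slice
                        ci_events.append((ci, int(counts[lo:hi].sum())))
        return ci_events

    def _stimulus_current(self, pop, t_now):
        i_extra = 0.0
        for st in self.spec.stimuli:
            if st.population != pop.name:
                continue
            if st.start_ms < t_now <= st.stop_ms:
                if np.isscalar(i_extra):
                    i_extra = np.zeros(pop.size)
                hi = st.hi if st.hi is not None else pop.size
                i_extra[st.lo:hi] += st.current
        return i_extra

    # ------------------------------------------------------------------- run
    def run(self, duration: Optional[float] = None,
            record_v: Optional[tuple] = None) -> RunResult:
        """Run for ``duration`` ms (default: the spec's); return results."""
        duration = duration if duration is not None else self.spec.duration
        n_steps = int(round(duration / self.dt))
        result = RunResult(len(self.alloc.cores), max(n_steps, 1))
        if record_v is not None:
            result.v_trace = np.zeros((n_steps,))
        for k in range(n_steps):
            self.step(result)
            if record_v is not None:
                pop_name, idx = record_v
                result.v_trace[k] = self.states[pop_name].v[idx]
        result.weights = self.final_weights()
        result.lost_entries = sum(
            h.lost_entries for u in self.units if u.histories
            for h in u.histories)
        return result

    def final_weights(self) -> dict:
        """Plastic weights as {projection index: [(pre_gid, post_gid, w)]}.

        Weights are as of each row's last update, sorted for comparability.
        """
        out: dict = {}
        for unit in self.units:
            if unit.kind != "stdp":
                continue
            post_off = self.offsets[unit.pop_name] + unit.lo
            for gid, (row, _cfg, pi) in unit.rows.items():
                trips = out.setdefault(pi, [])
                for j, w in zip(row.post_idx, row.weight):
                    trips.append((gid, post_off + int(j), float(w)))
        for pi in out:
            out[pi].sort()
        return out


def run(spec: NetworkSpec, alloc: Optional[CoreAllocation] = None,
        duration: Optional[float] = None,
        history_capacity: Optional[int] = plast.DEFAULT_HISTORY_CAPACITY,
        enable_flush: bool = True, record_v: Optional[tuple] = None) -> RunResult:
    """Partition (if needed) and run a network; convenience front end."""
    eng = Engine(spec, alloc, history_capacity=history_capacity,
                 enable_flush=enable_flush)
    return eng.run(duration, record_v=record_v)
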
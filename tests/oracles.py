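"""Independent oracles used by the test suite.

``online_stdp`` is a from-scratch all-pairs trace STDP implementation that
applies every weight update at the moment of the spike (nothing deferred);
``run_deferred_pair`` drives the package's deferred row-update machinery
over the same spike trains; ``ReferenceSimulator`` is a monolithic
(unpartitioned) network simulator that shares only the plasticity kernel
functions with the engine, used to cross-check the virtual-core dataflow.
"""

from __future__ import annotations

import math

import numpy as np

from spikemap.network import NetworkSpec, SynapticRow, sample_row
from spikemap.plasticity import (FlushPolicy, PlasticityConfig, PostHistory,
                                 flush_check, process_row)
from spikemap.simcore import (LifDecay, NeuronState, lif_step,
                              poisson_spike_prob, step_rng)

FRACTION_BITS = 16
SCALE = float(1 << FRACTION_BITS)


# ---------------------------------------------------------------------------
# Online all-pairs STDP oracle (single synapse)
# ---------------------------------------------------------------------------

def online_stdp(pre, post, cfg: PlasticityConfig, w0: float = 0.5) -> float:
    """Final weight from applying every pair interaction at spike time.

    Tie-break at simultaneous spikes: the post spike is handled first
    (potentiation against the previous pre spike, then post-trace update),
    then the pre spike (depression against the post trace including the
    simultaneous spike, then pre-trace update).
    """
    w, s_i, s_j, t_i, t_j = w0, 0.0, 0.0, None, None
    for t, kind in sorted([(t, 0) for t in post] + [(t, 1) for t in pre]):
        if kind == 0:
            if t_i is not None:
                w = min(cfg.w_max,
                        w + cfg.a_plus * s_i * math.exp(-(t - t_i) / cfg.tau_plus))
            s_j = ((s_j * math.exp(-(t - t_j) / cfg.tau_minus)
                    if t_j is not None else 0.0) + 1.0)
            t_j = t
        else:
            if t_j is not None:
                w = max(cfg.w_min,
                        w - cfg.a_minus * s_j * math.exp(-(t - t_j) / cfg.tau_minus))
            s_i = ((s_i * math.exp(-(t - t_i) / cfg.tau_plus)
                    if t_i is not None else 0.0) + 1.0)
            t_i = t
    return w


def flush_schedule(pre, policy: FlushPolicy, duration: float,
                   dt: float = 1.0) -> list:
    """Flush times from per-step silence monitoring of the pre neuron."""
    out = []
    last, t, i = 0.0, 0.0, 0
    pre = sorted(pre)
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        t += dt
        while i < len(pre) and pre[i] <= t:
            last = max(last, pre[i])
            i += 1
        if flush_check(t, last, policy):
            out.append(t)
            last = t
    return out


def run_deferred_pair(pre, post, cfg: PlasticityConfig, w0: float = 0.5,
                      capacity=None, flushes: bool = False,
                      max_rate: float = 200.0, duration=None):
    """Drive the deferred algorithm for one pre/post pair.

    Post entries are recorded as they happen; each pre spike (and, when
    enabled, each flush) runs the row update.  A terminal flush settles any
    unreplayed history so the result is comparable with the online oracle.
    Returns ``(final weight, lost history entries)``.
    """
    row = SynapticRow(0, np.array([0]), np.array([1]), np.array([w0]),
                      plastic=True)
    hist = PostHistory(capacity)
    t_end = (max(list(pre) + list(post)) if (len(pre) or len(post)) else 0.0) + 1.0
    if duration is None:
        duration = t_end
    events = [(t, 0, "post") for t in post] + [(t, 2, "pre") for t in pre]
    if flushes:
        policy = FlushPolicy(max_rate=max_rate,
                             buffer_size=capacity or 10)
        events += [(t, 1, "flush") for t in flush_schedule(pre, policy, duration)]
    for t, _, kind in sorted(events):
        if kind == "post":
            hist.add_post_spike(t, cfg)
        else:
            process_row(t, kind == "flush", row, [hist], None, cfg)
            hist.mark_consumed(row.t_last_update)
    process_row(max(duration, t_end), True, row, [hist], None, cfg)
    return float(row.weight[0]), hist.lost_entries


# ---------------------------------------------------------------------------
# Monolithic reference network simulator
# ---------------------------------------------------------------------------

class ReferenceSimulator:
    """Unpartitioned simulator sharing only the plasticity kernel.

    One global delay-slot accumulator per (population, receptor), integer
    fixed point; per-neuron post histories; rows fetched whole per
    presynaptic spike.  Matches the engine's event-time conventions: a
    spike emitted with timestamp t is processed one step later and lands
    ``delay - 1`` slots ahead, so its effect arrives at t + delay*dt.
    """

    def __init__(self, spec: NetworkSpec, history_capacity=10,
                 enable_flush: bool = True):
        self.spec = spec
        self.dt = spec.dt
        self.offsets = {}
        off = 0
        for p in spec.populations:
            self.offsets[p.name] = off
            off += p.size
        self.pop_index = {p.name: i for i, p in enumerate(spec.populations)}
        self.depth = spec.max_delay + 1
        self.acc = {}
        self.states = {}
        self.decays = {}
        for p in spec.populations:
            if p.is_source:
                continue
            for rec in p.params.tau_syn:
                self.acc[(p.name, rec)] = np.zeros((self.depth, p.size),
                                                   dtype=np.int64)
            v0 = None
            if p.v_init is not None:
                _, lo, hi = p.v_init
                rng = step_rng(spec.seed, 2000 + self.pop_index[p.name], 0)
                v0 = rng.uniform(lo, hi, size=p.size)
            self.states[p.name] = NeuronState.create(p.size, p.params, v0)
            self.decays[p.name] = LifDecay.create(p.params, spec.dt)
        # rows: per projection, per pre id
        self.rows = {}
        self.plastic_rows = {}
        self.histories = {}
        for pi, proj in enumerate(spec.projections):
            pre = spec.population(proj.pre)
            for pre_id in range(pre.size):
                post_ids, delays, weights = sample_row(spec, pi, pre_id)
                if len(post_ids) == 0:
                    continue
                if proj.plasticity is None:
                    self.rows.setdefault((pi, pre_id), (
                        post_ids, delays,
                        np.rint(weights * SCALE).astype(np.int64)))
                else:
                    self.plastic_rows[(pi, pre_id)] = SynapticRow(
                        pre_id=pre_id, post_idx=post_ids, delay=delays,
                        weight=weights.copy(), plastic=True)
            if proj.plasticity is not None:
                key = (proj.post, proj.plasticity)
                if key not in self.histories:
                    self.histories[key] = [
                        PostHistory(history_capacity)
                        for _ in range(spec.population(proj.post).size)]
        self.enable_flush = enable_flush
        self.policy = FlushPolicy(max_rate=spec.max_rate,
                                  buffer_size=history_capacity or 10)
        self.flush_pops = ({proj.pre for proj in spec.projections
                            if proj.plasticity is not None}
                           if enable_flush else set())
        self.last_event = {name: np.zeros(spec.population(name).size)
                           for name in self.flush_pops}
        self.head = 0
        self.pending = []        # (gid, flush) from last step

    class _Insert:
        def __init__(self, outer, pop, rec):
            self.outer, self.pop, self.rec = outer, pop, rec

        def insert(self, neuron, delay, weight):
            o = self.outer
            slot = (o.head + delay - 1) % o.depth
            o.acc[(self.pop, self.rec)][slot, neuron] += int(round(weight * SCALE))

    def run(self, duration: float):
        spec = self.spec
        n_steps = int(round(duration / self.dt))
        times, gids = [], []
        for k in range(n_steps):
            t_proc = k * self.dt
            t_now = (k + 1) * self.dt
            events = sorted(self.pending)
            # post-history entries first (simultaneity convention)
            for gid, fl in events:
                if fl:
                    continue
                for (pop_name, cfg_name), hists in self.histories.items():
                    lo = self.offsets[pop_name]
                    size = spec.population(pop_name).size
                    if lo <= gid < lo + size:
                        cfg = spec.plasticity_configs[cfg_name]
                        hists[gid - lo].add_post_spike(t_proc, cfg)
            # row processing
            for gid, fl in events:
                for pi, proj in enumerate(spec.projections):
                    pre_pop = spec.population(proj.pre)
                    lo = self.offsets[proj.pre]
                    if not (lo <= gid < lo + pre_pop.size):
                        continue
                    pre_id = gid - lo
                    if proj.plasticity is None:
                        if fl:
                            continue
                        row = self.rows.get((pi, pre_id))
                        if row is None:
                            continue
                        post_ids, delays, wfix = row
                        slots = (self.head + delays - 1) % self.depth
                        np.add.at(self.acc[(proj.post, proj.receptor)],
                                  (slots, post_ids), wfix)
                    else:
                        row = self.plastic_rows.get((pi, pre_id))
                        if row is None:
                            continue
                        cfg = spec.plasticity_configs[proj.plasticity]
                        ins = self._Insert(self, proj.post, proj.receptor)
                        process_row(t_proc, fl, row,
                                    self.histories[(proj.post, proj.plasticity)],
                                    ins, cfg)
            # drain + neuron update
            emitted = []
            for p in spec.populations:
                if p.is_source:
                    prob = poisson_spike_prob(p.source_rate, self.dt)
                    rng = step_rng(spec.seed, self.pop_index[p.name], k)
                    spiking = np.nonzero(rng.random(p.size) < prob)[0]
                else:
                    drained = {}
                    for rec in p.params.tau_syn:
                        a = self.acc[(p.name, rec)]
                        drained[rec] = a[self.head].copy() / SCALE
                        a[self.head] = 0
                    i_extra = self._stimulus(p, t_now)
                    bg = p.background
                    if bg is not None:
                        rng = step_rng(spec.seed,
                                       1000 + self.pop_index[p.name], k)
                        counts = rng.binomial(
                            bg.n_sources_per_neuron,
                            poisson_spike_prob(bg.rate, self.dt), size=p.size)
                        wfix = int(round(bg.weight * SCALE))
                        drained[bg.receptor] = (
                            drained.get(bg.receptor, 0.0)
                            + counts.astype(np.int64) * wfix / SCALE)
                    mask = lif_step(self.states[p.name], drained, p.params,
                                    self.dt, self.decays[p.name], i_extra)
                    spiking = np.nonzero(mask)[0]
                off = self.offsets[p.name]
                for idx in spiking:
                    emitted.append((off + int(idx), False))
                times.extend([t_now] * len(spiking))
                gids.extend((off + spiking).tolist())
                if p.name in self.flush_pops:
                    last = self.last_event[p.name]
                    last[spiking] = t_now
                    due = np.nonzero(t_now - last >= self.policy.threshold_ms)[0]
                    emitted.extend((off + int(i), True) for i in due)
                    last[due] = t_now
            self.pending = emitted
            self.head = (self.head + 1) % self.depth
        return np.asarray(times), np.asarray(gids, dtype=np.int64)

    def _stimulus(self, pop, t_now):
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

    def final_weights(self):
        out = {}
        for (pi, pre_id), row in self.plastic_rows.items():
            proj = self.spec.projections[pi]
            pre_off = self.offsets[proj.pre]
            post_off = self.offsets[proj.post]
            trips = out.setdefault(pi, [])
            for j, w in zip(row.post_idx, row.weight):
                trips.append((pre_off + pre_id, post_off + int(j), float(w)))
        for pi in out:
            out[pi].sort()
        return out
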
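"""Deferred, event-driven pair-based STDP with postsynaptic history and flushing.

Synaptic weights live with their row and are only touched when the row is
fetched, i.e. when the presynaptic neuron spikes (or emits a flush event).
All pre/post spike-pair interactions that happened since the row was last
updated are then replayed from a fixed-capacity, per-postsynaptic-neuron
history queue of ``(spike time, trace)`` entries.

The rule itself is all-to-all pair-based STDP with an additive weight
dependence: exponentially filtered spike traces on both sides, potentiation
``a_plus * s_i * exp(-dt/tau_plus)`` at each post spike, depression
``a_minus * s_j * exp(-dt/tau_minus)`` at each pre spike, and hard clipping
to ``[0, w_max]``.

Because the history queue is finite, entries can be lost when the
postsynaptic neuron fires much faster than the presynaptic one.  A *flush*
event -- the presynaptic neuron's id with a flag bit set, emitted after
``bufferSize`` maximum-rate interspike intervals of silence -- forces the
row to replay (and thus free) the accumulated history without acting as a
spike.  Lost entries are always counted, never dropped silently.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

DEFAULT_HISTORY_CAPACITY = 10


@dataclass
class PlasticityConfig:
    """Pair-based additive STDP parameters.

    Defaults are the conventional balanced-but-depression-dominated choice
    for this rule; ``w_max`` must be set to the scale of the projection it
    governs.
    """

    tau_plus: float = 20.0    # potentiation trace time constant, ms
    tau_minus: float = 20.0   # depression trace time constant, ms
    a_plus: float = 0.01
    a_minus: float = 0.012
    w_max: float = 1.0
    w_min: float = 0.0


class PostHistory:
    """Fixed-capacity circular queue of (t_j, s_j) postsynaptic entries.

    ``s_j`` stores the post trace *including* the entry's own spike.  When
    full, the oldest entry is overwritten.  An overwritten entry is *lost*
    only if some efferent row still needed it, i.e. if its time is past the
    ``consumed_until`` watermark -- the minimum ``t_last_update`` over the
    rows sharing this history, advanced via :meth:`mark_consumed` after
    spikes or flushes replay the queue.  Losses are counted, never silent.
    """

    __slots__ = ("capacity", "entries", "lost_entries", "consumed_until")

    def __init__(self, capacity: int = DEFAULT_HISTORY_CAPACITY):
        if capacity is not None and capacity < 1:
            raise ValueError("history capacity must be >= 1 (or None)")
        self.capacity = capacity
        self.entries: deque = deque(maxlen=capacity)
        self.lost_entries = 0
        self.consumed_until = -math.inf

    def __len__(self) -> int:
        return len(self.entries)

    def mark_consumed(self, t: float) -> None:
        """All entries at or before ``t`` have been replayed by every row."""
        self.consumed_until = max(self.consumed_until, t)

    def add_post_spike(self, t: float, config: PlasticityConfig) -> None:
        """Append a post spike at time ``t``, updating the post trace."""
        if self.entries:
            t_prev, s_prev = self.entries[-1]
            if t < t_prev:
                raise ValueError(
                    f"post spikes must be time-ordered (got {t} after {t_prev})")
            s = s_prev * math.exp(-(t - t_prev) / config.tau_minus) + 1.0
        else:
            s = 1.0
        if self.capacity is not None and len(self.entries) == self.capacity:
            if self.entries[0][0] > self.consumed_until:
                self.lost_entries += 1  # deque maxlen drops the oldest
        self.entries.append((t, s))

    def entries_between(self, t_lo: float, t_hi: float) -> list:
        """Entries with ``t_lo < t_j <= t_hi`` (replay interval convention)."""
        return [(tj, sj) for tj, sj in self.entries if t_lo < tj <= t_hi]

    def last_at_or_before(self, t: float) -> Optional[tuple]:
        """Most recent entry with ``t_j <= t``, or None."""
        for tj, sj in reversed(self.entries):
            if tj <= t:
                return (tj, sj)
        return None


@dataclass
class FlushPolicy:
    """When a silent neuron must flush its efferent rows.

    The threshold is ``bufferSize`` times the interspike interval at the
    network's assumed maximum firing rate: a neuron silent that long could
    have let a same-capacity history queue overflow downstream.
    """

    max_rate: float                 # Hz
    buffer_size: int = DEFAULT_HISTORY_CAPACITY

    @property
    def threshold_ms(self) -> float:
        return self.buffer_size * 1000.0 / self.max_rate

    def threshold_steps(self, dt: float) -> int:
        return max(1, int(round(self.threshold_ms / dt)))


def flush_check(t: float, t_last_event: float, policy: FlushPolicy) -> bool:
    """Emit a flush at ``t``?  ``t_last_event`` = later of last spike / flush.

    The timer re-arms after every flush (callers update ``t_last_event``).
    """
    return (t - t_last_event) >= policy.threshold_ms


# ---------------------------------------------------------------------------
# The four STDP kernel functions
# ---------------------------------------------------------------------------

def add_pre_spike(s_i: float, t: float, t_last_spike: Optional[float],
                  config: PlasticityConfig) -> float:
    """Pre-trace update at a presynaptic spike: decay then increment."""
    if t_last_spike is None:
        return 1.0
    return s_i * math.exp(-(t - t_last_spike) / config.tau_plus) + 1.0


def apply_post_spike(w: float, t_j: float, t_last_spike: Optional[float],
                     s_i: float, config: PlasticityConfig) -> float:
    """Potentiation from a post spike at ``t_j`` against the last pre spike.

    No-op until a presynaptic spike has occurred.
    """
    if t_last_spike is None:
        return w
    dw = config.a_plus * s_i * math.exp(-(t_j - t_last_spike) / config.tau_plus)
    return min(config.w_max, w + dw)


def apply_pre_spike(w: float, t: float, t_j: Optional[float], s_j: float,
                    config: PlasticityConfig) -> float:
    """Depression from a pre spike at ``t`` against the post entry ``(t_j, s_j)``.

    No-op when the history holds no entry at or before ``t``.
    """
    if t_j is None:
        return w
    dw = config.a_minus * s_j * math.exp(-(t - t_j) / config.tau_minus)
    return max(config.w_min, w - dw)


# ---------------------------------------------------------------------------
# Deferred row update
# ---------------------------------------------------------------------------

def process_row(t: float, flush: bool, row, histories, ring,
                config: PlasticityConfig):
    """Replay deferred plasticity for one row at a pre spike or flush event.

    For every synapse in the row, all post-history entries in
    ``(t_last_update, t]`` are applied as potentiation steps against the
    row's last presynaptic spike.  If the event is a real spike (not a
    flush), depression against the most recent post entry is then applied,
    the updated weight is inserted into the ring buffer at the synapse's
    delay, and finally the row header (pre trace, last-spike time) is
    advanced.  A flush replays history and advances ``t_last_update`` only.

    Parameters
    ----------
    t
        Event time, ms; must be >= ``row.t_last_update``.
    histories
        Sequence of :class:`PostHistory`, indexed by the row's local post
        indices.
    ring
        Object with ``insert(neuron, delay, weight)``; ignored for flushes.
        May be ``None`` when only the weight update is wanted.

    Returns
    -------
    (row, ring)
        The same objects, mutated in place (returned for chaining).
    """
    if t < row.t_last_update:
        raise ValueError(
            f"events must be processed in time order: t={t} < "
            f"t_last_update={row.t_last_update}")
    for k in range(len(row.post_idx)):
        j = int(row.post_idx[k])
        w = float(row.weight[k])
        hist = histories[j]
        for t_j, s_j in hist.entries_between(row.t_last_update, t):
            w = apply_post_spike(w, t_j, row.t_last_spike, row.s_i, config)
        if not flush:
            last = hist.last_at_or_before(t)
            if last is not None:
                w = apply_pre_spike(w, t, last[0], last[1], config)
            if ring is not None:
                ring.insert(j, int(row.delay[k]), w)
        row.weight[k] = w
    if not flush:
        row.s_i = add_pre_spike(row.s_i, t, row.t_last_spike, config)
        row.t_last_spike = t
    row.t_last_update = t
    return row, ring
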
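"""Time-driven LIF dynamics, Poisson sources, fixed-point ring buffers.

The ring buffer is the delay mechanism: a synaptic weight inserted with
delay ``d`` sits in a circular, per-neuron accumulator slot until ``d``
drains later, when it joins the neuron's synaptic current.  Accumulation is
*fixed-point* (integer, default 16 fraction bits) so that the drained total
is exactly independent of insertion order -- the property that makes spike
rasters bit-identical across different partitionings of the same network.

Neuron dynamics use the per-step closed-form (exponential) update of the
LIF membrane equation with the total input current held constant over the
step, which reproduces the analytic constant-input solution exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import NeuronParams

DEFAULT_FRACTION_BITS = 16
DEFAULT_RING_DEPTH = 16
#: Saturation bound of an accumulator, in fixed-point units (32-bit signed).
ACCUMULATOR_MAX = 2**31 - 1


class RingBuffer:
    """Delay-indexed fixed-point accumulator, one lane per neuron.

    ``depth`` is the maximum supported delay in steps; one extra physical
    slot ensures a maximal-delay insert never aliases the slot currently
    being drained.  Weights are accumulated as 64-bit integers in units of
    ``2**-fraction_bits`` and saturated to 32-bit range at drain time, so
    any permutation of a step's inserts drains bit-identically.
    """

    def __init__(self, n_neurons: int, depth: int = DEFAULT_RING_DEPTH,
                 fraction_bits: int = DEFAULT_FRACTION_BITS):
        if depth < 1:
            raise ValueError("ring depth must be >= 1")
        self.n_neurons = n_neurons
        self.depth = depth
        self.fraction_bits = fraction_bits
        self._scale = float(1 << fraction_bits)
        self._slots = np.zeros((depth + 1, n_neurons), dtype=np.int64)
        self._head = 0  # slot the next drain() will return

    # -- fixed-point conversion --------------------------------------------
    def to_fixed(self, w) -> np.ndarray:
        return np.rint(np.asarray(w, dtype=np.float64) * self._scale).astype(np.int64)

    def from_fixed(self, acc) -> np.ndarray:
        return np.asarray(acc, dtype=np.float64) / self._scale

    # -- insertion ----------------------------------------------------------
    def _slot(self, offset: int) -> int:
        return (self._head + offset) % (self.depth + 1)

    def insert(self, neuron: int, delay: int, weight: float) -> None:
        """Add ``weight`` for ``neuron``, visible at the ``delay``-th
        subsequent drain (``delay = 1`` means the very next drain).

        ``delay`` must be in ``[1, depth]``.
        """
        if not (1 <= delay <= self.depth):
            raise ValueError(f"delay {delay} outside [1, {self.depth}]")
        self._slots[self._slot(delay - 1), neuron] += self.to_fixed(weight)

    def insert_offset(self, post_idx, offsets, weights_fixed) -> None:
        """Vectorised insert at drain offsets (0 = the very next drain).

        Used by the engine, where routing already consumed one step of each
        projection delay.  ``weights_fixed`` are integer fixed-point values.
        """
        offsets = np.asarray(offsets)
        if offsets.size and (offsets.min() < 0 or offsets.max() > self.depth):
            raise ValueError("offset outside [0, depth]")
        slots = (self._head + offsets) % (self.depth + 1)
        np.add.at(self._slots, (slots, np.asarray(post_idx)), weights_fixed)

    # -- drain --------------------------------------------------------------
    def drain_fixed(self) -> np.ndarray:
        """Return the current slot as saturated fixed-point ints and advance."""
        out = self._slots[self._head].copy()
        np.clip(out, -ACCUMULATOR_MAX, ACCUMULATOR_MAX, out=out)
        self._slots[self._head] = 0
        self._head = (self._head + 1) % (self.depth + 1)
        return out

    def drain(self) -> np.ndarray:
        """Drain the current slot, converted to real weight units."""
        return self.from_fixed(self.drain_fixed())


# ---------------------------------------------------------------------------
# Neuron state and dynamics
# ---------------------------------------------------------------------------

@dataclass
class NeuronState:
    """Vectorised state of a population of LIF neurons."""

    v: np.ndarray                      # membrane potential, mV
    refrac_remaining: np.ndarray       # steps left in refractory period
    i_syn: dict                        # receptor -> current array
    t_last_own_spike: np.ndarray       # ms; -inf if never (flush bookkeeping)

    @classmethod
    def create(cls, n: int, params: NeuronParams,
               v_init: Optional[np.ndarray] = None) -> "NeuronState":
        v = (np.full(n, params.v_rest, dtype=np.float64) if v_init is None
             else np.asarray(v_init, dtype=np.float64).copy())
        return cls(
            v=v,
            refrac_remaining=np.zeros(n, dtype=np.int64),
            i_syn={rec: np.zeros(n) for rec in params.tau_syn},
            t_last_own_spike=np.full(n, -np.inf),
        )


@dataclass
class LifDecay:
    """Precomputed per-step decay factors for one (params, dt) pair."""

    alpha_m: float                 # exp(-dt/tau_m)
    alpha_syn: dict                # receptor -> exp(-dt/tau_syn)
    refrac_steps: int

    @classmethod
    def create(cls, params: NeuronParams, dt: float) -> "LifDecay":
        return cls(
            alpha_m=float(np.exp(-dt / params.tau_m)),
            alpha_syn={r: float(np.exp(-dt / tau))
                       for r, tau in params.tau_syn.items()},
            refrac_steps=int(round(params.t_refrac / dt)),
        )


def lif_step(state: NeuronState, drained_input: dict, params: NeuronParams,
             dt: float, decay: Optional[LifDecay] = None,
             i_extra=0.0) -> np.ndarray:
    """Advance one population by one time step; return the spike mask.

    Per-receptor synaptic currents decay by ``exp(-dt/tau_syn)`` and then
    receive the drained ring-buffer input.  The membrane then integrates the
    total current with the exact exponential propagator (current held
    constant over the step):

        v' = v_rest + I*R + (v - v_rest - I*R) * exp(-dt/tau_m)

    Threshold crossings emit a spike, reset ``v`` and start the refractory
    counter.  ``i_extra`` adds stimulus/DC current on top of ``i_offset``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if decay is None:
        decay = LifDecay.create(params, dt)

    i_total = np.full_like(state.v, params.i_offset, dtype=np.float64)
    for rec, alpha in decay.alpha_syn.items():
        cur = state.i_syn[rec]
        cur *= alpha
        inp = drained_input.get(rec)
        if inp is not None:
            if not np.all(np.isfinite(inp)):
                bad = int(np.nonzero(~np.isfinite(np.asarray(inp)))[0][0])
                raise ValueError(f"non-finite synaptic input at neuron {bad}")
            cur += inp
        i_total += cur
    i_total += i_extra

    refractory = state.refrac_remaining > 0
    v_inf = params.v_rest + i_total * params.r_membrane
    state.v = np.where(refractory, params.v_reset,
                       v_inf + (state.v - v_inf) * decay.alpha_m)
    state.refrac_remaining[refractory] -= 1

    spiked = (~refractory) & (state.v >= params.v_thresh)
    state.v[spiked] = params.v_reset
    state.refrac_remaining[spiked] = decay.refrac_steps
    return spiked


# ---------------------------------------------------------------------------
# Poisson sources
# ---------------------------------------------------------------------------

def poisson_spike_prob(rate: float, dt: float) -> float:
    """Per-step spike probability of a Poisson process: 1 - exp(-rate*dt)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return -np.expm1(-rate * dt * 1e-3)  # dt in ms


def poisson_step(rate: float, dt: float, rng: np.random.Generator,
                 n: int = 1) -> np.ndarray:
    """Bernoulli spike draw(s) for ``n`` independent sources over one step."""
    return rng.random(n) < poisson_spike_prob(rate, dt)


def step_rng(seed: int, domain: int, step: int) -> np.random.Generator:
    """Counter-based stream keyed by (seed, domain, step).

    Backs background/source draws so realised input is a function of the
    network spec alone, never of how cores were partitioned.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(0xA0, domain, step))
    return np.random.Generator(np.random.Philox(ss))


# ---------------------------------------------------------------------------
# Raster I/O (plain text: "time_ms neuron_global_id")
# ---------------------------------------------------------------------------

def write_raster(path, times, gids, header: str = "") -> None:
    """Write a spike raster as two-column text with a comment header."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# time_ms neuron_global_id\n")
        for t, g in zip(times, gids):
            fh.write(f"{t:.3f} {int(g)}\n")


def read_raster(path):
    """Read a raster written by :func:`write_raster`; returns (times, gids)."""
    times, gids = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, g = line.split()
            times.append(float(t))
            gids.append(int(g))
    return np.asarray(times), np.asarray(gids, dtype=np.int64)
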
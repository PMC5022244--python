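import math

import numpy as np
import pytest

import spikemap as sm
from spikemap.network import SynapticRow
from spikemap.plasticity import (FlushPolicy, PostHistory, add_pre_spike,
                                 apply_post_spike, apply_pre_spike,
                                 flush_check, process_row)

from .oracles import flush_schedule, online_stdp, run_deferred_pair

CFG = sm.PlasticityConfig(tau_plus=20.0, tau_minus=20.0, a_plus=0.01,
                          a_minus=0.012, w_max=1.0)


class TestTraces:
    def test_first_post_spike_starts_trace_at_one(self):
        h = PostHistory(10)
        h.add_post_spike(10.0, CFG)
        assert h.entries[-1] == (10.0, 1.0)

    def test_post_trace_recurrence(self):
        # spikes at 0 and 20 ms with tau_minus = 20 ms: exp(-1) + 1
        h = PostHistory(10)
        h.add_post_spike(0.0, CFG)
        h.add_post_spike(20.0, CFG)
        assert h.entries[-1][1] == pytest.approx(math.exp(-1) + 1, abs=1e-12)

    def test_pre_trace_recurrence(self):
        assert add_pre_spike(0.0, 5.0, None, CFG) == 1.0
        assert add_pre_spike(1.0, 20.0, 0.0, CFG) == pytest.approx(
            math.exp(-1) + 1, abs=1e-12)
        assert add_pre_spike(1.0, 1e7, 0.0, CFG) == pytest.approx(1.0)

    def test_history_overflow_counts_lost_entries(self):
        h = PostHistory(10)
        for k in range(11):
            h.add_post_spike(float(k), CFG)
        assert len(h) == 10
        assert h.lost_entries == 1

    def test_consumed_entries_are_not_counted_lost(self):
        h = PostHistory(10)
        for k in range(10):
            h.add_post_spike(float(k), CFG)
        h.mark_consumed(9.0)
        h.add_post_spike(10.0, CFG)
        assert h.lost_entries == 0

    def test_post_spikes_must_be_ordered(self):
        h = PostHistory(10)
        h.add_post_spike(5.0, CFG)
        with pytest.raises(ValueError, match="time-ordered"):
            h.add_post_spike(4.0, CFG)


class TestKernel:
    def test_potentiation_noop_without_pre_spike(self):
        assert apply_post_spike(0.3, 10.0, None, 1.0, CFG) == 0.3

    def test_potentiation_formula(self):
        # dt = 10 ms, tau_plus = 20 ms: 0.01 * exp(-0.5)
        w = apply_post_spike(0.0, 10.0, 0.0, 1.0, CFG)
        assert w == pytest.approx(0.01 * math.exp(-0.5), abs=1e-12)

    def test_potentiation_clips_at_w_max(self):
        assert apply_post_spike(0.9999999, 1.0, 0.9, 5.0, CFG) == CFG.w_max

    def test_depression_noop_with_empty_history(self):
        assert apply_pre_spike(0.01, 30.0, None, 0.0, CFG) == 0.01

    def test_depression_formula(self):
        # dt = 20 ms, tau_minus = 20 ms: 0.01 - 0.012 * exp(-1)
        w = apply_pre_spike(0.01, 20.0, 0.0, 1.0, CFG)
        assert w == pytest.approx(0.01 - 0.012 * math.exp(-1), abs=1e-12)

    def test_depression_clips_at_zero(self):
        assert apply_pre_spike(0.001, 1.0, 0.9, 5.0, CFG) == 0.0


def make_row(w=0.5, n=1):
    return SynapticRow(0, np.arange(n), np.ones(n, dtype=np.int64),
                       np.full(n, float(w)), plastic=True)


class _SpyRing:
    def __init__(self):
        self.calls = []

    def insert(self, neuron, delay, weight):
        self.calls.append((neuron, delay, weight))


class TestProcessRow:
    def test_flush_touches_no_ring_and_keeps_pre_state(self):
        row = make_row()
        hist = [PostHistory(10)]
        ring = _SpyRing()
        process_row(50.0, True, row, hist, ring, CFG)
        assert ring.calls == []
        assert row.t_last_spike is None
        assert row.t_last_update == 50.0

    def test_spike_with_empty_history_inserts_unchanged_weight(self):
        row = make_row(w=0.25)
        ring = _SpyRing()
        process_row(10.0, False, row, [PostHistory(10)], ring, CFG)
        assert ring.calls == [(0, 1, 0.25)]
        assert row.s_i == 1.0 and row.t_last_spike == 10.0

    def test_three_spike_interaction_matches_online_oracle(self):
        # pre 0, post 10, pre 30 (tau = 20 ms): one potentiation applied at
        # the second pre event, then one depression, exactly as online.
        pre, post = [0.0, 30.0], [10.0]
        w_def, _ = run_deferred_pair(pre, post, CFG)
        assert w_def == online_stdp(pre, post, CFG)

    def test_out_of_order_event_rejected(self):
        row = make_row()
        process_row(20.0, False, row, [PostHistory(10)], None, CFG)
        with pytest.raises(ValueError, match="time order"):
            process_row(10.0, False, row, [PostHistory(10)], None, CFG)

    @pytest.mark.parametrize("trial", range(20))
    def test_deferred_equals_online_on_random_trains(self, trial):
        rng = np.random.default_rng(1000 + trial)
        pre = np.sort(rng.uniform(0, 500, rng.integers(0, 30))).tolist()
        post = np.sort(rng.uniform(0, 500, rng.integers(0, 30))).tolist()
        w_def, lost = run_deferred_pair(pre, post, CFG)
        assert lost == 0
        assert w_def == pytest.approx(online_stdp(pre, post, CFG), abs=1e-14)

    def test_simultaneous_pre_and_post_spikes(self):
        pre = [10.0, 20.0]
        post = [10.0, 20.0]
        w_def, _ = run_deferred_pair(pre, post, CFG)
        assert w_def == pytest.approx(online_stdp(pre, post, CFG), abs=1e-14)

    def test_weights_stay_within_bounds(self):
        strong = sm.PlasticityConfig(a_plus=0.5, a_minus=0.6, w_max=1.0)
        rng = np.random.default_rng(77)
        for _ in range(10):
            pre = np.sort(rng.uniform(0, 300, 40)).tolist()
            post = np.sort(rng.uniform(0, 300, 40)).tolist()
            w, _ = run_deferred_pair(pre, post, strong)
            assert 0.0 <= w <= strong.w_max

    def test_lone_pre_spikes_never_change_weight(self):
        w, _ = run_deferred_pair([5.0, 50.0, 400.0], [], CFG, w0=0.37)
        assert w == 0.37


class TestFlush:
    def test_threshold_is_buffer_times_max_rate_isi(self):
        policy = FlushPolicy(max_rate=100.0, buffer_size=10)
        assert policy.threshold_ms == 100.0
        assert not flush_check(99.0, 0.0, policy)
        assert flush_check(100.0, 0.0, policy)

    def test_neuron_at_max_rate_never_flushes(self):
        policy = FlushPolicy(max_rate=100.0, buffer_size=10)
        pre = [10.0 * k for k in range(1, 101)]      # exactly 100 Hz
        assert flush_schedule(pre, policy, 1000.0) == []

    def test_silent_neuron_flushes_ten_times_per_second(self):
        policy = FlushPolicy(max_rate=100.0, buffer_size=10)
        sched = flush_schedule([], policy, 1000.0)
        assert sched == [100.0 * k for k in range(1, 11)]

    def test_flush_prevents_history_loss_and_preserves_weights(self):
        # pre ~1 Hz, post at a regular 100 Hz, capacity 10: without flushes
        # the queue overflows and the result drifts from the online oracle;
        # with flushes no needed entry is lost and the weight is exact.
        rng = np.random.default_rng(5)
        dur = 10000.0
        pre = np.sort(rng.uniform(0, dur, 10)).round(1).tolist()
        post = [5.0 + 10.0 * k for k in range(int(dur // 10))]
        w_oracle = online_stdp(pre, post, CFG)
        w_on, lost_on = run_deferred_pair(pre, post, CFG, capacity=10,
                                          flushes=True, max_rate=200.0,
                                          duration=dur)
        w_off, lost_off = run_deferred_pair(pre, post, CFG, capacity=10,
                                            flushes=False, duration=dur)
        assert lost_on == 0
        assert w_on == pytest.approx(w_oracle, abs=1e-12)
        assert lost_off > 0
        assert abs(w_off - w_oracle) > 1e-6
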
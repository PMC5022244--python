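import math

import numpy as np
import pytest

import spikemap as sm
from spikemap.mapping import (CostConstants, InfeasiblePartitionError,
                              RateAssumptions, audit_allocation,
                              count_synapse_processors,
                              estimate_standard_neurons_per_core,
                              partition_standard, partition_synapse_centric,
                              synproc_capacity)

CLOCK = 200e6


class TestStandardEstimate:
    def test_plastic_24khz_gives_49_neurons(self):
        assert estimate_standard_neurons_per_core(
            1.0, 24000.0, plastic=True, h=1.0) == 49

    def test_static_24khz_capped_at_256(self):
        # uncapped model value is floor(200e6 / (181e3 + 21*24e3)) = 291
        raw = math.floor(CLOCK / (181e3 + 21 * 24000))
        assert raw == 291
        assert estimate_standard_neurons_per_core(1.0, 24000.0) == 256

    def test_zero_input_static_hits_cap(self):
        assert estimate_standard_neurons_per_core(1.0, 1e-9) == 256


class TestSynprocCapacity:
    def test_static_peak_throughput(self):
        assert synproc_capacity(1024, "static", per_row=0) == pytest.approx(
            CLOCK / 15)

    def test_stdp_peak_throughput(self):
        assert synproc_capacity(512, "stdp", h=1.0, per_row=0) == pytest.approx(
            CLOCK / 137)

    def test_row_aware_capacity(self):
        got = synproc_capacity(102.4, "static")  # default 800 cycles/row
        assert got == pytest.approx(CLOCK / (15 + 800 / 102.4))

    def test_capacity_increases_with_row_length(self):
        caps = [synproc_capacity(n, "static") for n in (10, 100, 1000)]
        assert caps == sorted(caps)


class TestCountProcessors:
    def test_static_full_connectivity_peak_model(self):
        assert count_synapse_processors(1024, 24000, 24000, 1024,
                                        "static", per_row=0) == 2

    def test_stdp_full_connectivity_peak_model(self):
        assert count_synapse_processors(512, 24000, 24000, 512,
                                        "stdp", per_row=0) == 9

    def test_static_sparse_with_row_overhead(self):
        assert count_synapse_processors(1024, 24000, 240000, 102.4,
                                        "static") == 3

    @pytest.mark.parametrize("n_post,mu,rows,rlen,kind", [
        (1024, 24000, 24000, 1024, "static"),
        (1024, 24000, 240000, 102.4, "static"),
        (512, 24000, 120000, 102.4, "stdp"),
        (512, 24000, 24000, 512, "stdp"),
    ])
    def test_count_is_minimal(self, n_post, mu, rows, rlen, kind):
        # brute force: k-1 processors must overrun the clock, k must not
        costs = CostConstants()
        k = count_synapse_processors(n_post, mu, rows, rlen, kind)
        per_event = costs.per_event(kind, 1.0)
        per_row = costs.per_row(kind)
        total = n_post * mu * per_event + rows * per_row
        assert total / k <= CLOCK
        if k > 1:
            assert total / (k - 1) > CLOCK

    def test_monotone_in_row_length_and_rate(self):
        total_events = 1024 * 24000
        ks = [count_synapse_processors(1024, 24000, total_events / rlen, rlen,
                                       "static") for rlen in (16, 64, 256, 1024)]
        assert ks == sorted(ks, reverse=True)
        ks = [count_synapse_processors(1024, mu, 24000, 1024, "static")
              for mu in (6000, 12000, 24000, 48000)]
        assert ks == sorted(ks)

    def test_indivisible_row_is_infeasible(self):
        with pytest.raises(InfeasiblePartitionError):
            count_synapse_processors(1024, 24000, 10, 100000, "static",
                                     step_budget_cycles=200e3)


class TestPartition:
    def test_vogels_abbott_10k_core_counts(self):
        spec = sm.make_vogels_abbott(10000, 0.02)
        s = partition_synapse_centric(spec).summary()
        assert (s["neuron_cores"], s["synapse_cores"], s["total_cores"]) == \
            (10, 20, 30)

    def test_vogels_abbott_80k_core_counts(self):
        spec = sm.make_vogels_abbott(80000, 0.1)
        s = partition_synapse_centric(spec).summary()
        assert (s["neuron_cores"], s["synapse_cores"], s["total_cores"]) == \
            (157, 314, 471)

    def test_standard_10k_uses_40_cores(self):
        spec = sm.make_vogels_abbott(10000, 0.02)
        assert partition_standard(spec).summary()["total_cores"] == 40

    def test_minimal_network_gets_one_of_each(self):
        params = sm.NeuronParams(tau_syn={"exc": 5.0})
        spec = sm.NetworkSpec(
            populations=[sm.Population("a", 10, params=params),
                         sm.Population("b", 20, params=params)],
            projections=[sm.Projection("a", "b", p=0.5, weight=0.01)])
        alloc = partition_synapse_centric(
            spec, RateAssumptions(mean_rate_hz=1.0))
        assert alloc.n_synapse_cores == 1
        assert alloc.n_neuron_cores == 2  # one per population

    def test_every_neuron_and_row_owned_exactly_once(self):
        spec = sm.make_vogels_abbott(10000, 0.02)
        alloc = partition_synapse_centric(spec)
        for pop in spec.populations:
            covered = sorted(
                c.slice for c in alloc.by_role("neuron")
                if c.population == pop.name)
            assert covered[0][0] == 0 and covered[-1][1] == pop.size
            for (a, b), (c, d) in zip(covered, covered[1:]):
                assert b == c
        # each (projection, pre, post) pair is held by exactly one core
        for pop in spec.populations:
            for key in {(c.kind, c.receptor, c.plasticity)
                        for c in alloc.by_role("synapse")
                        if c.population == pop.name}:
                cores = [c for c in alloc.by_role("synapse")
                         if c.population == pop.name
                         and (c.kind, c.receptor, c.plasticity) == key]
                seen = set()
                for c in cores:
                    for (pi, lo, hi) in c.sources:
                        for pre in range(lo, hi):
                            cell = (pi, pre, c.slice)
                            assert cell not in seen
                            seen.add(cell)

    def test_plastic_population_halves_neuron_processors(self):
        # a 24 kHz STDP workload needs >= 4 synapse processors per 1024
        # posts, which forces 512-neuron neuron processors
        params = sm.NeuronParams(tau_syn={"exc": 5.0})
        spec = sm.NetworkSpec(
            populations=[sm.Population("src", 2400, source_rate=10.0),
                         sm.Population("post", 1024, params=params)],
            projections=[sm.Projection("src", "post", p=1.0, weight=0.001,
                                       plasticity="stdp")],
            plasticity_configs={"stdp": sm.PlasticityConfig(w_max=0.01)})
        alloc = partition_synapse_centric(spec)
        post_cores = [c for c in alloc.by_role("neuron")
                      if c.population == "post"]
        assert all(c.slice[1] - c.slice[0] <= 512 for c in post_cores)

    def test_synapse_core_estimates_fit_budget(self):
        spec = sm.make_vogels_abbott(80000, 0.1)
        alloc = partition_synapse_centric(spec)
        budget = alloc.step_budget_cycles
        for c in alloc.cores:
            assert c.est_cycles_per_step <= budget


class TestAudit:
    def _toy_alloc(self):
        params = sm.NeuronParams(tau_syn={"exc": 5.0})
        spec = sm.NetworkSpec(
            populations=[sm.Population("a", 100, params=params),
                         sm.Population("b", 100, params=params)],
            projections=[sm.Projection("a", "b", p=0.5, weight=0.01)])
        return partition_synapse_centric(spec, RateAssumptions(1.0))

    def test_idle_network_far_under_budget(self):
        alloc = self._toy_alloc()
        activity = {i: {"events": np.zeros(10), "rows": np.zeros(10)}
                    for i in range(len(alloc.cores))}
        rep = audit_allocation(alloc, activity)
        assert rep["overruns"] == 0
        assert all(c["headroom"] > 0.5 for c in rep["cores"])

    def test_overload_is_flagged(self):
        alloc = self._toy_alloc()
        syn = next(i for i, c in enumerate(alloc.cores) if c.role == "synapse")
        activity = {syn: {"events": np.full(10, 2e5), "rows": np.full(10, 100.0)}}
        rep = audit_allocation(alloc, activity)
        assert rep["overruns"] >= 1
        assert rep["cores"][syn]["overrun"]

    def test_core_at_computed_capacity_sits_at_budget_edge(self):
        # feed a synapse core exactly the event/row rates its capacity
        # model says it can sustain: the audit should place it within
        # [90%, 100%] of the step budget, with no overrun
        alloc = self._toy_alloc()
        syn = next(i for i, c in enumerate(alloc.cores) if c.role == "synapse")
        row_len = 102.4
        cap = synproc_capacity(row_len, "static")          # events/s
        ev_step = cap * alloc.dt * 1e-3
        rows_step = ev_step / row_len
        activity = {syn: {"events": np.full(10, ev_step),
                          "rows": np.full(10, rows_step)}}
        rep = audit_allocation(alloc, activity)
        worst = rep["cores"][syn]["worst_cycles"]
        budget = rep["budget_cycles_per_step"]
        assert 0.9 * budget <= worst <= budget * (1 + 1e-9)
        assert not rep["cores"][syn]["overrun"]
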
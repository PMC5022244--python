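import numpy as np
import pytest

import spikemap as sm


def small_mixed_network(n_exc=160, n_inh=40, seed=7, duration=150.0,
                        bg_weight=0.15):
    """A small balanced network with one plastic and two static projections.

    Background Poisson keeps both populations firing so plastic, static and
    flush paths are all exercised.
    """
    params = sm.NeuronParams(
        tau_m=20.0, v_rest=-65.0, v_thresh=-50.0, v_reset=-65.0,
        t_refrac=2.0, r_membrane=20.0, tau_syn={"exc": 5.0, "inh": 10.0})
    bg = sm.BackgroundInputSpec(rate=10.0, n_sources_per_neuron=120,
                                weight=bg_weight, receptor="exc")
    return sm.NetworkSpec(
        populations=[
            sm.Population("exc", n_exc, params=params, background=bg),
            sm.Population("inh", n_inh, params=params, background=bg),
        ],
        projections=[
            sm.Projection("exc", "exc", p=0.1, weight=0.02, delay=2,
                          receptor="exc", plasticity="stdp"),
            sm.Projection("exc", "inh", p=0.1, weight=0.03, delay=1,
                          receptor="exc"),
            sm.Projection("inh", "exc", p=0.2, weight=-0.1, delay=1,
                          receptor="inh"),
        ],
        plasticity_configs={"stdp": sm.PlasticityConfig(w_max=0.05)},
        dt=1.0, duration=duration, max_rate=100.0, seed=seed)


@pytest.fixture
def mixed_net():
    return small_mixed_network()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
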
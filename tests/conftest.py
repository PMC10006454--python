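import numpy as np
import pytest

import spikecog as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net():
    """3-neuron network with default parameters."""
    w, p = sc.make_fixture("tiny_net", seed=0)
    return w, p


@pytest.fixture
def short_timing():
    """Fast trial timing for unit tests (tens of steps)."""
    return sc.scaled_timing(stim_range=(20.0, 30.0), t_resp=10.0,
                            delay_range=(5.0, 10.0))


@pytest.fixture
def small_batch(rng, short_timing):
    cfg = sc.mse_config(n_batch=3)
    return sc.sample_batch(list(sc.ALL_TASKS[:6]), 3, rng, 0.05,
                           cfg.mask_values, short_timing), cfg
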
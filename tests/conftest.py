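import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_net_series():
    """One fixed 6-node ground truth and its binned 60-s simulation."""
    from spikegc import bin_spikes, generate_random_network, simulate

    conn = generate_random_network(6, 0.2, seed=42)
    raster = simulate(conn, duration=60_000.0, seed=7)
    return conn, bin_spikes(raster)


def var_chain(n_steps, coupling=0.8, noise=1.0, seed=0, lag=1):
    """Driver y and driven x with x_k = coupling * y_{k-lag} + noise."""
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n_steps)
    x = rng.standard_normal(n_steps) * noise
    x[lag:] += coupling * y[:-lag]
    return x, y
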
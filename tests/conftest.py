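import numpy as np
import pytest

from depna.timeseries import NodeTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gaussian_panel_factory():
    """Panels of correlated Gaussian nodes with a known factor structure."""

    def make(n_nodes=5, n_time=200, seed=0, loading=0.6):
        rng = np.random.default_rng(seed)
        common = rng.standard_normal(n_time)
        noise = rng.standard_normal((n_nodes, n_time))
        samples = loading * common + np.sqrt(1 - loading**2) * noise
        labels = [f"n{i}" for i in range(n_nodes)]
        return NodeTimeSeries(labels, samples)

    return make


@pytest.fixture
def white_panel_factory():
    """Panels of mutually independent white-noise nodes."""

    def make(n_nodes=4, n_time=100, seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"n{i}" for i in range(n_nodes)]
        return NodeTimeSeries(labels, rng.standard_normal((n_nodes, n_time)))

    return make
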
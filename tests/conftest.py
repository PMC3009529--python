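import numpy as np
import pytest

from ltvgrn.ltv_core import ExpressionSeriesSet, LTVParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_params(rng):
    """A random 3-gene parameter set within the default search bounds."""
    n = 3
    return LTVParameters(
        alpha=rng.uniform(-10, 10, (n, n)),
        beta=rng.uniform(-3, 3, (n, n)),
        phi=rng.uniform(-np.pi / 2, np.pi / 2, (n, n)),
        omega=rng.uniform(-np.pi / 2, np.pi / 2, n),
    )


@pytest.fixture
def self_generated_data(random_params):
    """Noise-free data rolled out by the model itself (free run, 2 replicates)."""
    from ltvgrn.ltv_core import simulate_trajectory

    series = []
    for x0 in ([0.2, 0.5, 0.8], [0.9, 0.1, 0.4]):
        series.append(simulate_trajectory(random_params, x0=np.array(x0), T=8))
    return ExpressionSeriesSet(series=series, times=np.arange(8, dtype=float), gene_names=["G1", "G2", "G3"])
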
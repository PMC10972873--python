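import numpy as np
import pytest

from rbnres.network import Reservoir, ReservoirSpec


def toy_reservoir(sources, weights, sigma_star=1.0, input_scale=1.0, seed=0):
    """Hand-built reservoir from explicit (N, K) source/weight arrays."""
    sources = np.asarray(sources, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    N, K = sources.shape
    spec = ReservoirSpec(N=N, K=K, sigma_star=sigma_star,
                         input_scale=input_scale, seed=seed)
    return Reservoir(spec=spec, sources=sources, weights=weights)


@pytest.fixture
def mutual_pair():
    """Two neurons feeding each other with weight +1 (state period 2)."""
    return toy_reservoir([[1], [0]], [[1.0], [1.0]])
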
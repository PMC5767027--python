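import numpy as np
import pytest
from hypothesis import settings

from agame.pool_sim import PoolSpec, run_benchmark

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_benchmark():
    """The full default benchmark grid (3 pool sizes x 3 fragmentations x
    2 coverage modes x 100 replicates, fixed seed). Shared session-wide
    because it is the costly part of the suite."""
    table, per_rep = run_benchmark(PoolSpec())
    return table, per_rep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
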
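import numpy as np
import pytest

from dcrank import DistributedDataset, KernelSpec, Shard


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def kernel():
    return KernelSpec()


@pytest.fixture
def small_shard(rng):
    """A random 6 x 3 shard with mild signal, used for gradient checks."""
    X = rng.standard_normal((6, 3))
    beta = np.array([1.0, -0.5, 0.0])
    Y = X @ beta + 0.3 * rng.standard_normal(6)
    return Shard(X, Y, machine_id=1)


@pytest.fixture
def two_shard_dataset(rng):
    """Two shards of 3 rows each (30 ordered pooled pairs)."""
    X = rng.standard_normal((6, 2))
    Y = X @ np.array([1.0, 2.0]) + rng.standard_normal(6)
    return DistributedDataset.from_arrays(X, Y, m=2)
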
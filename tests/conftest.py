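import numpy as np
import pytest

from ecgrank import DatasetSpec, SplitSpec, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """300-beat moderately noisy dataset shared across tests."""
    spec = DatasetSpec(n_per_class={0: 90, 1: 210}, seed=11, name="small")
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return split_dataset(small_dataset, SplitSpec(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
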
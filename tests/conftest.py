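import numpy as np
import pytest

from sevc import (Dataset, ConstructRecord, SyntheticConfig,
                  generate_dataset, load_fixture_library)


@pytest.fixture(scope="session")
def raw_library():
    return load_fixture_library()


@pytest.fixture(scope="session")
def library(raw_library):
    """The bundled fixture scales, normalized and oriented."""
    return raw_library.normalized()


@pytest.fixture(scope="session")
def grid_dataset():
    """A full 71x8 noise-free synthetic grid with its ground truth."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture
def tiny_dataset():
    """A hand-built 2x2 labeled grid with short sequences."""
    records = [
        ConstructRecord("c1", 1, 1, "ARNDAKLR", 1),
        ConstructRecord("c2", 1, 2, "ARNDCKIR", 1),
        ConstructRecord("c3", 2, 1, "IIIVVKLR", 0),
        ConstructRecord("c4", 2, 2, "ILIVFKIR", 0),
    ]
    return Dataset(records, n_inserts=2, n_strategies=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
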
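import numpy as np
import pytest

from apn.synthetic_tasks import SynthSpec, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A 300-molecule, 12-task motif benchmark (9 train / 3 test)."""
    spec = SynthSpec(n_molecules=300, seed=42)
    table, split = make_benchmark(spec, n_train_tasks=9, n_test_tasks=3)
    return spec, table, split


@pytest.fixture(scope="session")
def smiles300(small_benchmark):
    _, table, _ = small_benchmark
    return table["smiles"].tolist()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
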
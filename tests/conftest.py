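import numpy as np
import pytest

from bibs.bisulfite import build_bisulfite_indexes
from bibs.simulate import random_genome


@pytest.fixture(scope="session")
def small_genome():
    """200 kb seeded random genome for search-level tests."""
    return random_genome(200_000, seed=42)


@pytest.fixture(scope="session")
def small_indexes(small_genome):
    return build_bisulfite_indexes(small_genome)


@pytest.fixture(scope="session")
def bench_genome():
    """2 Mb seeded random genome for the end-to-end sensitivity checks."""
    return random_genome(2_000_000, seed=1)


@pytest.fixture(scope="session")
def bench_indexes(bench_genome):
    return build_bisulfite_indexes(bench_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
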
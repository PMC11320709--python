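import numpy as np
import pytest

from invmap import Reference, build_index

BASES = np.array(list("ACGT"))


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def genome() -> str:
    return random_dna(20_000, seed=1234)


@pytest.fixture(scope="session")
def reference(genome) -> Reference:
    return Reference([("chr1", genome)])


@pytest.fixture(scope="session")
def index_w1(reference):
    return build_index(reference, k=15, w=1)


@pytest.fixture(scope="session")
def index_w5(reference):
    return build_index(reference, k=15, w=5)
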
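import numpy as np
import pytest

from poresieve import IbfParams, InterleavedBloomFilter, build_index, generate_reference
from poresieve.ibf import Fragment


@pytest.fixture(scope="session")
def small_reference():
    """One 250 kb random record -> 3 bins at default fragment geometry."""
    return generate_reference(1, [250_000], 0.5, seed=7)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return build_index([], IbfParams(), records=small_reference)


@pytest.fixture()
def toy_ibf():
    """A 3-bin, k=7 filter sized generously (FP ~ 1e-9), empty on arrival."""
    params = IbfParams(k=7, h=3, p=1e-9, fragment_size=64, overlap=6)
    frags = [Fragment(f"f{i}", 0, 64, i) for i in range(3)]
    return InterleavedBloomFilter(params, frags)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
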
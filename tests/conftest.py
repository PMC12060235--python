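import numpy as np
import pytest

from pinebreed import GenotypeMatrix, syndata


@pytest.fixture
def small_cfg():
    """A small but structurally complete synthetic cohort configuration."""
    return syndata.SimConfig(
        n_loci=300,
        regions={"ES1": 6, "ES2": 6, "ES3": 6, "ES6": 6},
        n_registered=8,
        ramets_per_registered=(4, 6),
        years=tuple(range(2012, 2018)),
        test_ramets_per_clone=4,
        seed=42,
    )


@pytest.fixture
def small_dataset(small_cfg):
    return syndata.simulate_dataset(small_cfg)


@pytest.fixture
def tiny_matrix():
    """6 samples x 10 loci with known calls, incl. missing."""
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
    calls[0, 0] = -1
    calls[3, 5] = -1
    return GenotypeMatrix(
        [f"s{i}" for i in range(6)], [f"L{j}" for j in range(10)], calls
    )
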
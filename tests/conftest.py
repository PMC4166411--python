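import numpy as np
import pytest

from cgifaire import SyntheticConfig, generate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (fixed seed), shared across the suite."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast per-module tests."""
    cfg = SyntheticConfig(
        seed=7,
        chrom_lengths={"chr1": 200_000, "chr2": 200_000},
        n_islands=40,
        n_noncgi_sites=10,
        island_min_gap=2000,
        library_size_treatment=40_000,
        library_size_control=40_000,
    )
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
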
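import numpy as np
import pytest

from phistruct import GeneratorConfig, generate_full_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic dataset shared by read-only tests."""
    config = GeneratorConfig(
        n_per_genus=6,
        n_outgroup=6,
        families_per_genus=2,
        embed_dim=64,
        length_median=180,
        length_spread=25,
        seed=11,
    )
    return generate_full_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
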
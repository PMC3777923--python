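import numpy as np
import pytest

from pplink import RVKDEParams, SynthConfig, generate_bundle, train_model


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 4 pathways x 6 genes, 12 reference organisms."""
    return SynthConfig(
        n_pathways=4,
        genes_per_pathway=6,
        n_reference_organisms=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_model(small_bundle):
    return train_model(small_bundle, RVKDEParams(alpha=1.0, beta=1.0, ks=3, kt=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
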
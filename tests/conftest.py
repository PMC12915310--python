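import numpy as np
import pytest

from micromulti.simulate import EffectSizes, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_truth():
    """A small but complete synthetic bundle shared across tests."""
    cfg = SimConfig(
        n_strains=10,
        n_gcfs=25,
        n_features=60,
        genes_per_genome=180,
        bgc_per_genome=8,
        effect_sizes=EffectSizes(
            sigma_medium=1.0, sigma_phylo=0.3, sigma_source=0.0, sigma_noise=0.3
        ),
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
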
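import numpy as np
import pytest

from richddi import (Hyperparameters, SyntheticConfig, generate_kg, split_ddi,
                     train)


@pytest.fixture(scope="session")
def tiny_config():
    """A 10-entity KG: 6 drugs / 2 proteins, 3 relation types, vocab 8."""
    return SyntheticConfig(n_drugs=6, n_proteins=2, n_pathways=1,
                           n_phenotypes=1, n_relations=3, n_basic=8,
                           n_ddi_pairs=3, vocab_size=8, n_clusters=2,
                           labels_per_ddi=3, noise_sd=0.1, latent_dim=4,
                           seed=3)


@pytest.fixture(scope="session")
def tiny_kg(tiny_config):
    kg, truth = generate_kg(tiny_config)
    return kg


@pytest.fixture(scope="session")
def small_config():
    """A ~50-entity KG large enough for short training runs."""
    return SyntheticConfig(n_drugs=20, n_proteins=16, n_pathways=8,
                           n_phenotypes=4, n_relations=5, n_basic=150,
                           n_ddi_pairs=20, vocab_size=20, n_clusters=2,
                           labels_per_ddi=3, noise_sd=0.05, latent_dim=8,
                           seed=5)


@pytest.fixture(scope="session")
def small_kg(small_config):
    kg, truth = generate_kg(small_config)
    return kg


@pytest.fixture(scope="session")
def small_split(small_kg):
    return split_ddi(small_kg, 0.3, seed=11)


@pytest.fixture(scope="session")
def small_hp():
    return Hyperparameters(k=8, c=4, iterations=300, batch_size=64,
                           dropout=0.0, seed=2)


@pytest.fixture(scope="session")
def small_trained(small_split, small_hp):
    """One short training run shared across tests."""
    params, state = train(small_split.train_kg, small_hp)
    return params, state
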
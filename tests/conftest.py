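import numpy as np
import pytest

from rsmanet import (AffinityModelConfig, Providers, SyntheticSpec,
                     generate_dataset)


@pytest.fixture(scope="session")
def tiny_synthetic():
    """Small seeded dataset shared by read-only tests."""
    return generate_dataset(
        SyntheticSpec(n_rnas=6, n_mols=8, n_pairs=16, seed=1,
                      rna_len_range=(12, 25)))


@pytest.fixture(scope="session")
def overfit_synthetic():
    """8-pair fixture for capacity/ablation training tests."""
    return generate_dataset(
        SyntheticSpec(n_rnas=4, n_mols=6, n_pairs=8, seed=2,
                      rna_len_range=(15, 30)))


def tiny_config(**overrides) -> AffinityModelConfig:
    base = dict(d=16, d_pre=16, epochs=3, seed=3, batch_size=4,
                n_gat_layers=1, n_gat_heads=2, n_gcn_layers=2,
                n_transformer_blocks=1, n_transformer_heads=2,
                n_fusion_blocks=1, n_fusion_heads=2, dropout=0.2)
    base.update(overrides)
    return AffinityModelConfig(**base)


@pytest.fixture
def tiny_cfg():
    return tiny_config()


def providers_for(syn) -> Providers:
    return Providers(embedding=syn.embedding_provider,
                     contact_maps=syn.contact_maps)
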
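"""Desk-scale experiment protocols on synthetic data.

These are the package's standard self-checks: an overfit-capacity run on a
handful of pairs and a planted-signal recovery run with a label-permutation
control.  Both are fully seeded and sized to run on one CPU in minutes;
`docs/methods.md` records the problem sizes and what passing them does and
does not show about real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .data_io import AffinityPair, Dataset
from .evaluation import regression_metrics
from .model import (AffinityModelConfig, FeatureStore, Providers,
                    predict_batch, train)
from .synthetic_data import SyntheticSpec, generate_dataset


def desk_config(seed: int, **overrides) -> AffinityModelConfig:
    """Small-width configuration for desk-scale runs (d=32, shallow)."""
    base = dict(d=32, d_pre=16, seed=seed, n_gat_layers=1, n_gat_heads=2,
                n_gcn_layers=2, n_transformer_blocks=1,
                n_transformer_heads=2, n_fusion_blocks=1, n_fusion_heads=2)
    base.update(overrides)
    return AffinityModelConfig(**base)


@dataclass
class RecoveryResult:
    heldout_pcc: float
    rmse: float
    n_train: int
    n_test: int


def permute_labels(dataset: Dataset, seed: int) -> Dataset:
    """Shuffle affinities across pairs (signal-destroying control)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.affinities)
    pairs = [AffinityPair(p.rna_id, p.mol_id, float(y))
             for p, y in zip(dataset.pairs, perm)]
    return Dataset(dataset.rnas, dataset.molecules, pairs).validate()


def planted_signal_recovery(seed: int, permute: bool = False,
                            n_pairs: int = 500, noise_sd: float = 0.3,
                            test_fraction: float = 0.2,
                            epochs: int = 10) -> RecoveryResult:
    """Train on synthetic pairs with a planted pKd signal and measure
    held-out Pearson correlation; with `permute` the labels are shuffled
    first, so any apparent recovery would indicate leakage."""
    spec = SyntheticSpec(n_rnas=40, n_mols=60, n_pairs=n_pairs,
                         noise_sd=noise_sd, seed=seed)
    syn = generate_dataset(spec)
    ds = syn.dataset
    if permute:
        ds = permute_labels(ds, seed + 1)
    order = np.random.default_rng(seed + 2).permutation(len(ds.pairs))
    n_test = int(round(test_fraction * len(ds.pairs)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    cfg = desk_config(seed, epochs=epochs)
    prov = Providers(embedding=syn.embedding_provider,
                     contact_maps=syn.contact_maps)
    result = train(ds.subset(train_idx), cfg, prov)
    test_ds = ds.subset(test_idx)
    store = FeatureStore(test_ds, prov, cfg)
    scores = predict_batch(test_ds, result.model, store)
    pcc, _, rmse = regression_metrics(test_ds.affinities, scores)
    return RecoveryResult(pcc, rmse, len(train_idx), len(test_idx))


@dataclass
class OverfitResult:
    final_mse: float
    steps_to_threshold: Optional[int]   # None if never reached
    history: List[float]


def overfit_capacity(seed: int, n_pairs: int = 8, max_steps: int = 500,
                     mse_threshold: float = 0.01) -> OverfitResult:
    """Drive training MSE on a tiny fixture toward zero (capacity check).

    With batch size >= n_pairs each epoch is one optimizer step, so
    `max_steps` bounds the step count directly.  Dropout is disabled: the
    question is representational capacity, not regularized generalization.
    """
    syn = generate_dataset(
        SyntheticSpec(n_rnas=4, n_mols=6, n_pairs=n_pairs, seed=seed,
                      rna_len_range=(15, 30)))
    cfg = desk_config(seed + 3, epochs=max_steps, dropout=0.0,
                      batch_size=max(16, n_pairs))
    prov = Providers(embedding=syn.embedding_provider,
                     contact_maps=syn.contact_maps)
    result = train(syn.dataset, cfg, prov,
                   stop_below_train_mse=mse_threshold)
    history = [e["train_mse"] for e in result.history]
    reached = [i for i, m in enumerate(history) if m < mse_threshold]
    return OverfitResult(history[-1], reached[0] + 1 if reached else None,
                         history)
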
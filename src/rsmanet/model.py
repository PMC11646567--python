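"""End-to-end affinity predictor: four encoder streams, cross-fusion, and
the prediction head, plus training, batching, and checkpointing.

The head combines each entity's encoder-pooled and cross-fused vectors by
element-wise mean, concatenates the graph- and sequence-view results, and
applies a two-layer MLP (ReLU + dropout):

    R = MLP([mean(R̄^g, R̄^{c,g}), mean(R̄^s, R̄^{c,s})])
    M = MLP([mean(M̄^g, M̄^{c,g}), mean(M̄^s, M̄^{c,s})])
    ŷ = MLP([R, M])

Ablations: without the fusion module the cross terms are replaced by the
encoder pooled vectors (mean(x, x) = x), keeping all head shapes unchanged;
without the graph (or sequence) view the corresponding concatenation halves
are dropped and the MLPs are sized accordingly.

Training minimizes mean squared error with Adam (defaults: learning rate
5e-4, batch size 16, hidden width d = 128, dropout 0.2, weight decay 1e-7).
Minibatches are processed one pair at a time with the loss averaged over
the batch before a single backward pass, so predictions are exactly
batch-size independent.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._nn import MLPHead, Module
from ._optim import Adam
from ._tensor import Tensor, concat
from .cross_fusion import (AttentionMaps, CrossFusionEncoder,
                           CrossFusionOutput)
from .data_io import Dataset
from .featurization import (ATOM_FEATURE_DIM, ContactMap, EmbeddingProvider,
                            MockEmbeddingProvider, MolFeatures, RnaFeatures,
                            featurize_molecule, featurize_rna)
from .mol_encoder import MolEncoder
from .rna_encoder import RnaEncoder

logger = logging.getLogger(__name__)


@dataclass
class AffinityModelConfig:
    """Hyperparameters; defaults follow the published training setup where
    one is stated (lr, batch size, d, dropout, weight decay, kernel sizes)
    and declared package defaults elsewhere (depths, head counts)."""

    d: int = 128
    d_pre: int = 16
    kernel_sizes: Tuple[int, ...] = (7, 11, 15)
    lr: float = 5e-4
    batch_size: int = 16
    dropout: float = 0.2
    weight_decay: float = 1e-7
    epochs: int = 100
    seed: int = 0
    use_graph_view: bool = True
    use_sequence_view: bool = True
    use_fusion: bool = True
    n_gat_layers: int = 2
    n_gat_heads: int = 4
    leaky_slope: float = 0.2
    n_gcn_layers: int = 2
    n_transformer_blocks: int = 2
    n_transformer_heads: int = 4
    n_fusion_blocks: int = 1
    n_fusion_heads: int = 4
    early_stop_patience: int = 20
    contact_density: float = 0.05

    def __post_init__(self):
        if not (self.use_graph_view or self.use_sequence_view):
            raise ValueError("at least one view must be enabled")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")

    @property
    def n_views(self) -> int:
        return int(self.use_graph_view) + int(self.use_sequence_view)


@dataclass
class Providers:
    """Pluggable external feature sources.

    `embedding` supplies per-nucleotide pretrained embeddings; `contact_maps`
    maps rna_id to a precomputed ContactMap, with seeded synthetic maps
    (backbone + random long-range contacts) generated for any RNA not listed.
    """

    embedding: EmbeddingProvider
    contact_maps: Dict[str, ContactMap] = field(default_factory=dict)

    @classmethod
    def mock(cls, d_pre: int = 16, seed: int = 0) -> "Providers":
        return cls(embedding=MockEmbeddingProvider(d_pre=d_pre, seed=seed))


class FeatureStore:
    """Featurize each unique RNA/molecule once and cache the result."""

    def __init__(self, dataset: Dataset, providers: Providers,
                 config: AffinityModelConfig):
        self.dataset = dataset
        self.providers = providers
        self.config = config
        self._rna: Dict[str, RnaFeatures] = {}
        self._mol: Dict[str, MolFeatures] = {}

    def rna(self, rna_id: str) -> RnaFeatures:
        if rna_id not in self._rna:
            rec = self.dataset.rnas[rna_id]
            pre = self.providers.contact_maps.get(rna_id)
            if pre is not None:
                from .featurization import encode_rna_tokens
                feats = RnaFeatures(
                    rna_id=rna_id,
                    indices=encode_rna_tokens(rec),
                    contact=pre,
                    pretrained=self.providers.embedding(rec))
            else:
                # per-RNA deterministic seed so maps do not depend on order
                import hashlib
                h = hashlib.blake2b(rec.sequence.encode(),
                                    digest_size=4).digest()
                feats = featurize_rna(
                    rec, self.providers.embedding,
                    contact_source="synthetic",
                    contact_seed=int.from_bytes(h, "little"),
                    contact_density=self.config.contact_density)
            self._rna[rna_id] = feats
        return self._rna[rna_id]

    def mol(self, mol_id: str) -> MolFeatures:
        if mol_id not in self._mol:
            self._mol[mol_id] = featurize_molecule(self.dataset.molecules[mol_id])
        return self._mol[mol_id]


class AffinityModel(Module):
    """The assembled dual-view cross-fusion affinity predictor."""

    def __init__(self, config: AffinityModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d
        self.rna_encoder = RnaEncoder(
            d, config.d_pre, config.n_gat_layers, config.n_gat_heads,
            config.leaky_slope, config.kernel_sizes,
            config.use_graph_view, config.use_sequence_view, rng)
        self.mol_encoder = MolEncoder(
            d, ATOM_FEATURE_DIM, config.n_gcn_layers,
            config.n_transformer_blocks, config.n_transformer_heads,
            config.use_graph_view, config.use_sequence_view, rng)
        if config.use_fusion:
            self.fusion = CrossFusionEncoder(
                d, config.n_fusion_blocks, config.n_fusion_heads, rng)
        v = config.n_views
        self.rna_mlp = MLPHead(v * d, d, d, config.dropout, rng)
        self.mol_mlp = MLPHead(v * d, d, d, config.dropout, rng)
        self.out_mlp = MLPHead(2 * d, d, 1, config.dropout, rng)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def forward(self, rna_feats: RnaFeatures, mol_feats: MolFeatures,
                override_cross: Optional[CrossFusionOutput] = None
                ) -> Tuple[Tensor, Optional[AttentionMaps]]:
        """Predict pKd for one (RNA, molecule) pair.

        `override_cross` substitutes fixed cross-fusion outputs (used to
        verify ablation parity); ordinarily leave it None.
        """
        rna_views = self.rna_encoder(rna_feats)
        mol_views = self.mol_encoder(mol_feats.graph, mol_feats.tokens)
        maps: Optional[AttentionMaps] = None
        if override_cross is not None:
            cross = override_cross
            maps = cross.attention
        elif self.config.use_fusion:
            cross = self.fusion(rna_views, mol_views)
            maps = cross.attention
        else:
            cross = CrossFusionOutput(rna_views.Rg_pooled, rna_views.Rs_pooled,
                                      mol_views.Mg_pooled, mol_views.Ms_pooled,
                                      AttentionMaps())
        r_parts, m_parts = [], []
        if self.config.use_graph_view:
            r_parts.append((rna_views.Rg_pooled + cross.R_cg) * 0.5)
            m_parts.append((mol_views.Mg_pooled + cross.M_cg) * 0.5)
        if self.config.use_sequence_view:
            r_parts.append((rna_views.Rs_pooled + cross.R_cs) * 0.5)
            m_parts.append((mol_views.Ms_pooled + cross.M_cs) * 0.5)
        r_in = r_parts[0] if len(r_parts) == 1 else concat(r_parts, axis=0)
        m_in = m_parts[0] if len(m_parts) == 1 else concat(m_parts, axis=0)
        r_vec = self.rna_mlp(r_in.reshape(1, -1), self._dropout_rng)
        m_vec = self.mol_mlp(m_in.reshape(1, -1), self._dropout_rng)
        y_hat = self.out_mlp(concat([r_vec, m_vec], axis=1), self._dropout_rng)
        return y_hat.reshape(()), maps

    __call__ = forward


def predict_affinity(rna_feats: RnaFeatures, mol_feats: MolFeatures,
                     model: AffinityModel) -> Tuple[float, AttentionMaps]:
    """Deterministic eval-mode prediction with retained attention maps."""
    was_training = model.training
    model.eval()
    try:
        y, maps = model(rna_feats, mol_feats)
    finally:
        if was_training:
            model.train()
    return float(y.data), maps


def predict_batch(dataset: Dataset, model: AffinityModel,
                  store: FeatureStore) -> np.ndarray:
    """One eval-mode score per pair, order preserved."""
    was_training = model.training
    model.eval()
    try:
        out = np.empty(len(dataset.pairs))
        for i, pair in enumerate(dataset.pairs):
            y, _ = model(store.rna(pair.rna_id), store.mol(pair.mol_id))
            out[i] = float(y.data)
    finally:
        if was_training:
            model.train()
    return out


@dataclass
class TrainResult:
    model: AffinityModel
    optimizer: Adam
    history: List[Dict[str, float]]   # per epoch: train_mse, val_mse (if any)
    best_epoch: int


def _epoch_loss(model: AffinityModel, dataset: Dataset,
                store: FeatureStore) -> float:
    preds = predict_batch(dataset, model, store)
    return float(np.mean((preds - dataset.affinities) ** 2))


def train(dataset: Dataset, config: AffinityModelConfig, providers: Providers,
          val_dataset: Optional[Dataset] = None,
          model: Optional[AffinityModel] = None,
          stop_below_train_mse: Optional[float] = None) -> TrainResult:
    """Minibatch MSE training with Adam; seeded and reproducible.

    Early stopping on validation MSE (patience from config) applies only
    when `val_dataset` is given; the returned model carries the best
    validation-epoch weights in that case.
    """
    if not dataset.pairs:
        raise ValueError("empty training dataset")
    model = model if model is not None else AffinityModel(config)
    model.train()
    model.reseed_dropout(config.seed + 1)
    store = FeatureStore(dataset, providers, config)
    val_store = (FeatureStore(val_dataset, providers, config)
                 if val_dataset is not None else None)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    order_rng = np.random.default_rng(config.seed + 2)
    n = len(dataset.pairs)
    history: List[Dict[str, float]] = []
    best_val = np.inf
    best_state: Optional[Dict[str, np.ndarray]] = None
    best_epoch = -1
    patience_left = config.early_stop_patience
    for epoch in range(config.epochs):
        perm = order_rng.permutation(n)
        batch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            opt.zero_grad()
            loss = None
            for i in idx:
                pair = dataset.pairs[i]
                y, _ = model(store.rna(pair.rna_id), store.mol(pair.mol_id))
                sq = (y - pair.affinity) ** 2.0
                loss = sq if loss is None else loss + sq
            loss = loss / float(len(idx))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"last batch indices {idx.tolist()}")
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        entry = {"epoch": float(epoch), "train_mse": float(np.mean(batch_losses))}
        if val_dataset is not None:
            val_mse = _epoch_loss(model, val_dataset, val_store)
            entry["val_mse"] = val_mse
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_state = model.state()
                best_epoch = epoch
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
        history.append(entry)
        logger.debug("epoch %d: %s", epoch, entry)
        if (stop_below_train_mse is not None
                and entry["train_mse"] < stop_below_train_mse):
            break
        if val_dataset is not None and patience_left <= 0:
            break
    if best_state is not None:
        model.load_state(best_state)
    else:
        best_epoch = len(history) - 1
    return TrainResult(model, opt, history, best_epoch)


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(path: Union[str, Path], model: AffinityModel,
                    optimizer: Optional[Adam] = None, epoch: int = 0) -> None:
    """Single-file archive: config, parameters, optimizer state, RNG state."""
    arrays: Dict[str, np.ndarray] = {}
    for k, v in model.state().items():
        arrays["param/" + k] = v
    meta = {"config": asdict(model.config), "epoch": epoch,
            "dropout_rng": model._dropout_rng.bit_generator.state}
    if optimizer is not None:
        meta["opt_t"] = optimizer.t
        for k in optimizer.m:
            arrays["adam_m/" + k] = optimizer.m[k]
            arrays["adam_v/" + k] = optimizer.v[k]
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: Union[str, Path]
                    ) -> Tuple[AffinityModel, Optional[Adam], int]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        config = AffinityModelConfig(**cfg_dict)
        model = AffinityModel(config)
        model.load_state({k[len("param/"):]: npz[k] for k in npz.files
                          if k.startswith("param/")})
        model._dropout_rng.bit_generator.state = meta["dropout_rng"]
        optimizer = None
        if "opt_t" in meta:
            optimizer = Adam(model.parameters(), lr=config.lr,
                             weight_decay=config.weight_decay)
            optimizer.load_state({
                "t": meta["opt_t"],
                "m": {k[len("adam_m/"):]: npz[k] for k in npz.files
                      if k.startswith("adam_m/")},
                "v": {k[len("adam_v/"):]: npz[k] for k in npz.files
                      if k.startswith("adam_v/")},
            })
    return model, optimizer, int(meta["epoch"])
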
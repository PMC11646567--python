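"""End-to-end model: head composition, determinism, training behaviour,
checkpointing, and ablation variants."""

import numpy as np
import pytest

from rsmanet import (AffinityModel, AffinityModelConfig, FeatureStore,
                     Providers, load_checkpoint, predict_affinity,
                     predict_batch, save_checkpoint, train)
from rsmanet.cross_fusion import AttentionMaps, CrossFusionOutput

from conftest import providers_for, tiny_config


def stores_for(syn, cfg):
    return FeatureStore(syn.dataset, providers_for(syn), cfg)


def first_pair_feats(syn, cfg):
    store = stores_for(syn, cfg)
    pair = syn.dataset.pairs[0]
    return store.rna(pair.rna_id), store.mol(pair.mol_id)


def test_default_hyperparameters():
    """Published training setup: lr 5e-4, batch 16, d 128, dropout 0.2,
    weight decay 1e-7, kernel sizes 7/11/15."""
    cfg = AffinityModelConfig()
    assert cfg.lr == 5e-4
    assert cfg.batch_size == 16
    assert cfg.d == 128
    assert cfg.dropout == 0.2
    assert cfg.weight_decay == 1e-7
    assert cfg.kernel_sizes == (7, 11, 15)


def test_config_validation():
    with pytest.raises(ValueError, match="view"):
        AffinityModelConfig(use_graph_view=False, use_sequence_view=False)
    with pytest.raises(ValueError, match="dropout"):
        AffinityModelConfig(dropout=1.0)


def test_zero_parameters_give_zero_prediction(tiny_synthetic, tiny_cfg):
    model = AffinityModel(tiny_cfg)
    for name, p in model.parameters().items():
        p.data[:] = 0.0
    rna, mol = first_pair_feats(tiny_synthetic, tiny_cfg)
    y, _ = predict_affinity(rna, mol, model)
    assert y == 0.0


def test_eval_forward_deterministic(tiny_synthetic, tiny_cfg):
    model = AffinityModel(tiny_cfg)
    rna, mol = first_pair_feats(tiny_synthetic, tiny_cfg)
    y1, _ = predict_affinity(rna, mol, model)
    y2, _ = predict_affinity(rna, mol, model)
    assert y1 == y2


def test_head_composition_matches_numpy_oracle(tiny_synthetic, tiny_cfg):
    """Eval-mode ŷ equals the mean/concat/MLP composition computed with
    plain NumPy from the model's own weights."""
    model = AffinityModel(tiny_cfg)
    model.eval()
    rna, mol = first_pair_feats(tiny_synthetic, tiny_cfg)
    rv = model.rna_encoder(rna)
    mv = model.mol_encoder(mol.graph, mol.tokens)
    cross = model.fusion(rv, mv)

    def mlp(head, x):
        h = np.maximum(x @ head.W1.W.data + head.W1.b.data, 0.0)
        return h @ head.W2.W.data + head.W2.b.data

    r_in = np.concatenate([0.5 * (rv.Rg_pooled.data + cross.R_cg.data),
                           0.5 * (rv.Rs_pooled.data + cross.R_cs.data)])
    m_in = np.concatenate([0.5 * (mv.Mg_pooled.data + cross.M_cg.data),
                           0.5 * (mv.Ms_pooled.data + cross.M_cs.data)])
    r_vec = mlp(model.rna_mlp, r_in[None, :])
    m_vec = mlp(model.mol_mlp, m_in[None, :])
    expected = float(mlp(model.out_mlp,
                         np.concatenate([r_vec, m_vec], axis=1))[0, 0])
    y, _ = model(rna, mol)
    assert y.data == pytest.approx(expected, abs=1e-10)


def test_predict_batch_aligned_and_batch_independent(tiny_synthetic, tiny_cfg):
    model = AffinityModel(tiny_cfg)
    ds = tiny_synthetic.dataset.subset([0, 1, 2])
    store = FeatureStore(ds, providers_for(tiny_synthetic), tiny_cfg)
    scores = predict_batch(ds, model, store)
    assert scores.shape == (3,)
    for i, pair in enumerate(ds.pairs):
        y, _ = predict_affinity(store.rna(pair.rna_id),
                                store.mol(pair.mol_id), model)
        assert scores[i] == y   # per-sample processing: exact equality


def test_predict_batch_unknown_id_raises(tiny_synthetic, tiny_cfg):
    ds = tiny_synthetic.dataset
    store = FeatureStore(ds, providers_for(tiny_synthetic), tiny_cfg)
    with pytest.raises(KeyError):
        store.rna("no-such-rna")


def test_training_reduces_loss_and_is_deterministic(overfit_synthetic):
    cfg = tiny_config(epochs=8, dropout=0.0, batch_size=16)
    prov = providers_for(overfit_synthetic)
    res1 = train(overfit_synthetic.dataset, cfg, prov)
    res2 = train(overfit_synthetic.dataset, cfg, prov)
    h1 = [e["train_mse"] for e in res1.history]
    h2 = [e["train_mse"] for e in res2.history]
    assert h1 == h2                       # same seed, identical history
    assert h1[-1] < h1[0]                 # loss trend decreases


def test_training_with_validation_tracks_val_mse(tiny_synthetic):
    cfg = tiny_config(epochs=3)
    prov = providers_for(tiny_synthetic)
    ds = tiny_synthetic.dataset
    res = train(ds.subset(range(10)), cfg, prov,
                val_dataset=ds.subset(range(10, 16)))
    assert all("val_mse" in e for e in res.history)
    assert res.best_epoch >= 0


def test_nan_loss_aborts_with_diagnostics(tiny_synthetic):
    cfg = tiny_config(epochs=1)
    model = AffinityModel(cfg)
    next(iter(model.parameters().values())).data[:] = np.nan
    with pytest.raises(FloatingPointError, match="non-finite"):
        train(tiny_synthetic.dataset, cfg, providers_for(tiny_synthetic),
              model=model)


def test_checkpoint_round_trip_bit_identical(tmp_path, tiny_synthetic):
    cfg = tiny_config(epochs=2)
    prov = providers_for(tiny_synthetic)
    res = train(tiny_synthetic.dataset, cfg, prov)
    store = stores_for(tiny_synthetic, cfg)
    before = predict_batch(tiny_synthetic.dataset, res.model, store)
    path = tmp_path / "model.npz"
    save_checkpoint(path, res.model, res.optimizer, epoch=2)
    model2, opt2, epoch = load_checkpoint(path)
    after = predict_batch(tiny_synthetic.dataset, model2, store)
    assert np.array_equal(before, after)    # bit-identical
    assert epoch == 2
    assert opt2.t == res.optimizer.t


@pytest.mark.parametrize("variant", [
    {"use_fusion": False},
    {"use_graph_view": False},
    {"use_sequence_view": False},
])
def test_ablations_train_and_predict(overfit_synthetic, variant):
    """Every ablation variant trains end-to-end without shape errors."""
    cfg = tiny_config(epochs=2, **variant)
    prov = providers_for(overfit_synthetic)
    res = train(overfit_synthetic.dataset, cfg, prov)
    store = stores_for(overfit_synthetic, cfg)
    scores = predict_batch(overfit_synthetic.dataset, res.model, store)
    assert np.isfinite(scores).all()


def test_without_fusion_parity(tiny_synthetic):
    """With cross outputs frozen at the encoder pooled vectors, the full
    model's ŷ equals the fusion-free variant's exactly (mean(x, x) = x)."""
    cfg_full = tiny_config(use_fusion=True)
    cfg_nofusion = tiny_config(use_fusion=False)
    full = AffinityModel(cfg_full)
    nofu = AffinityModel(cfg_nofusion)
    # share every parameter the two variants have in common
    full_params = full.state()
    nofu.load_state({k: full_params[k] for k in nofu.parameters()})
    rna, mol = first_pair_feats(tiny_synthetic, cfg_full)
    full.eval()
    nofu.eval()
    rv = full.rna_encoder(rna)
    mv = full.mol_encoder(mol.graph, mol.tokens)
    frozen = CrossFusionOutput(rv.Rg_pooled, rv.Rs_pooled,
                               mv.Mg_pooled, mv.Ms_pooled, AttentionMaps())
    y_full, _ = full.forward(rna, mol, override_cross=frozen)
    y_nofu, _ = nofu.forward(rna, mol)
    assert y_full.data == pytest.approx(float(y_nofu.data), abs=1e-12)
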
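"""RNA encoders: graph-attention coefficients and aggregation against
scalar-arithmetic oracles; multiscale CNN against the index-by-index
convolution sum."""

import numpy as np
import pytest

from rsmanet import RNARecord
from rsmanet._tensor import Tensor, conv1d_same
from rsmanet.featurization import (ContactMap, MockEmbeddingProvider,
                                   RnaFeatures, encode_rna_tokens,
                                   synthetic_contact_map)
from rsmanet.rna_encoder import (GatEncoder, MultiscaleCnnEncoder, RnaEncoder,
                                 gat_attention_coefficients, gat_encode,
                                 multiscale_cnn_encode)

RNG = np.random.default_rng(7)


def make_features(seq: str, d_pre: int = 4, density: float = 0.3,
                  contact: np.ndarray = None) -> RnaFeatures:
    rna = RNARecord("r", seq)
    cm = (ContactMap("r", contact) if contact is not None
          else synthetic_contact_map(rna, seed=1, density=density))
    return RnaFeatures("r", encode_rna_tokens(rna), cm,
                       MockEmbeddingProvider(d_pre, seed=0)(rna))


def leaky(x, s=0.2):
    return np.where(x > 0, x, s * x)


def gat_attention_oracle(h, contact, W_d, a_src, a_dst, slope=0.2):
    """Scalar-arithmetic evaluation of the attention softmax over
    N(i) u {i}."""
    p = h.shape[0]
    support = contact + np.eye(p) > 0
    alpha = np.zeros((p, p))
    hd = h @ W_d
    for i in range(p):
        logits = {}
        for n in range(p):
            if support[i, n]:
                logits[n] = leaky(hd[i] @ a_src + hd[n] @ a_dst, slope)
        mx = max(logits.values())
        z = {n: np.exp(v - mx) for n, v in logits.items()}
        total = sum(z.values())
        for n, v in z.items():
            alpha[i, n] = v / total
    return alpha


def test_attention_equal_states_uniform():
    """Identical node states give equal weight to all four support members."""
    enc = GatEncoder(d=4, n_layers=1, n_heads=1,
                     rng=np.random.default_rng(0))
    contact = np.zeros((5, 5), dtype=int)
    contact[0, 1] = contact[1, 0] = 1
    contact[0, 2] = contact[2, 0] = 1
    contact[0, 3] = contact[3, 0] = 1
    cm = ContactMap("r", contact)
    states = Tensor(np.tile(RNG.standard_normal(4), (5, 1)))
    alpha = gat_attention_coefficients(enc, states, cm).data
    assert np.allclose(alpha[0, :4], 0.25)
    assert alpha[0, 4] == 0.0
    # node 4 is isolated: all mass on the self-loop
    assert alpha[4, 4] == pytest.approx(1.0)


def test_attention_matches_scalar_oracle():
    """Random 4-node graph, d=2: coefficients equal the loop oracle."""
    enc = GatEncoder(d=2, n_layers=1, n_heads=1,
                     rng=np.random.default_rng(3))
    contact = np.array([[0, 1, 1, 0], [1, 0, 0, 1],
                        [1, 0, 0, 0], [0, 1, 0, 0]])
    cm = ContactMap("r", contact)
    states = Tensor(RNG.standard_normal((4, 2)))
    head = enc.layers[0].heads[0]
    alpha = gat_attention_coefficients(enc, states, cm).data
    oracle = gat_attention_oracle(states.data, contact, head.W_d.W.data,
                                  head.a_src.data, head.a_dst.data)
    assert np.allclose(alpha, oracle, atol=1e-10)


def test_gat_single_node_reduces_to_linear_relu():
    """With one nucleotide, alpha_ii = 1 and the update is ReLU(W_a h)."""
    enc = GatEncoder(d=4, n_layers=1, n_heads=1,
                     rng=np.random.default_rng(1))
    feats = make_features("G", contact=np.zeros((1, 1), dtype=int))
    tokens, pooled = gat_encode(feats, enc)
    h0 = enc.embedding.table.data[2]
    expected = np.maximum(h0 @ enc.layers[0].heads[0].W_a.W.data, 0.0)
    assert np.allclose(tokens.data[0], expected)
    assert np.allclose(pooled.data, expected)


def test_gat_path_graph_matches_composed_oracle():
    """3-node path, one layer: output equals attention-oracle aggregation."""
    enc = GatEncoder(d=3, n_layers=1, n_heads=1,
                     rng=np.random.default_rng(9))
    contact = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    feats = make_features("ACG", contact=contact)
    tokens, _ = gat_encode(feats, enc)
    head = enc.layers[0].heads[0]
    h = enc.embedding.table.data[feats.indices]
    alpha = gat_attention_oracle(h, contact, head.W_d.W.data,
                                 head.a_src.data, head.a_dst.data)
    expected = np.maximum(alpha @ (h @ head.W_a.W.data), 0.0)
    assert np.allclose(tokens.data, expected, atol=1e-10)


def test_gat_rows_stochastic_all_layers_heads():
    enc = GatEncoder(d=8, n_layers=2, n_heads=4,
                     rng=np.random.default_rng(5))
    feats = make_features("ACGUACGUACGU")
    h = enc.embedding(feats.indices)
    for layer in enc.layers:
        for head in layer.heads:
            alpha = head.attention(h, feats.contact, layer.leaky_slope).data
            assert np.all(alpha >= 0)
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-5)
        h = layer(h, feats.contact)


def test_gat_permutation_equivariance():
    """Permuting nucleotides and the contact matrix permutes token rows and
    leaves the pooled vector unchanged."""
    enc = GatEncoder(d=6, n_layers=2, n_heads=2,
                     rng=np.random.default_rng(11))
    feats = make_features("ACGUACGUAC")
    tokens, pooled = gat_encode(feats, enc)
    perm = np.random.default_rng(2).permutation(feats.p)
    pm = feats.contact.matrix[np.ix_(perm, perm)]
    pfeats = RnaFeatures("r", feats.indices[perm], ContactMap("r", pm),
                         feats.pretrained[perm])
    ptokens, ppooled = gat_encode(pfeats, enc)
    assert np.allclose(ptokens.data, tokens.data[perm], atol=1e-8)
    assert np.allclose(ppooled.data, pooled.data, atol=1e-5)


@pytest.mark.parametrize("p", [1, 7, 50, 301])
def test_cnn_length_preserved(p):
    from rsmanet.featurization import MAX_RNA_LENGTH
    assert p <= MAX_RNA_LENGTH
    seq = ("ACGU" * ((p // 4) + 1))[:p]
    enc = MultiscaleCnnEncoder(d=4, d_pre=4, rng=np.random.default_rng(0))
    tokens, pooled = multiscale_cnn_encode(make_features(seq), enc)
    assert tokens.shape == (p, 4)
    assert pooled.shape == (4,)


def test_cnn_zero_input_zero_bias_gives_zero():
    enc = MultiscaleCnnEncoder(d=4, d_pre=4, conv_bias=False,
                               rng=np.random.default_rng(0))
    enc.embedding.table.data[:] = 0.0
    enc.pre_proj.W.data[:] = 0.0
    enc.pre_proj.b.data[:] = 0.0
    enc.proj1.b.data[:] = 0.0
    enc.proj2.b.data[:] = 0.0
    tokens, pooled = multiscale_cnn_encode(make_features("ACGUACG"), enc)
    assert np.allclose(tokens.data, 0.0)
    assert np.allclose(pooled.data, 0.0)


def test_conv_matches_summation_oracle():
    """conv1d_same with a flipped kernel equals the centered, zero-padded
    evaluation of the textbook convolution sum C(j) = sum_i I(j-i+k) K(i)."""
    k, p = 7, 3
    x = RNG.standard_normal((p, 1))
    w = RNG.standard_normal((k, 1, 1))
    y = conv1d_same(Tensor(x), Tensor(w)).data[:, 0]
    half = (k - 1) // 2
    xp = np.zeros(p + 2 * half)                 # symmetric zero padding
    xp[half:half + p] = x[:, 0]
    kern = w[::-1, 0, 0]                        # K is the flipped kernel
    expected = np.zeros(p)
    for j in range(p):
        for i in range(1, k + 1):               # C(j) = sum_i I(j-i+k) K(i)
            expected[j] += xp[j + k - i] * kern[i - 1]
    assert np.allclose(y, expected, atol=1e-12)


def test_cnn_branch_averaging_and_projection_formula():
    """Rs equals ReLU(W_c2 ReLU(W_c1 E)) with E the mean of the branches."""
    enc = MultiscaleCnnEncoder(d=3, d_pre=4, kernel_sizes=(3, 5),
                               rng=np.random.default_rng(4))
    feats = make_features("ACGUA")
    x = enc.input_signal(feats)
    b0 = conv1d_same(x, enc.kernels[0], enc.biases[0]).data
    b1 = conv1d_same(x, enc.kernels[1], enc.biases[1]).data
    e = 0.5 * (b0 + b1)
    h = np.maximum(e @ enc.proj1.W.data + enc.proj1.b.data, 0)
    expected = np.maximum(h @ enc.proj2.W.data + enc.proj2.b.data, 0)
    tokens, pooled = enc(feats)
    assert np.allclose(tokens.data, expected, atol=1e-12)
    assert np.allclose(pooled.data, expected.mean(axis=0), atol=1e-12)


def test_pooled_vectors_are_row_means():
    enc = RnaEncoder(d=8, d_pre=4, rng=np.random.default_rng(6))
    views = enc(make_features("ACGUACGUAC"))
    assert np.allclose(views.Rg_pooled.data,
                       views.Rg_tokens.data.mean(axis=0), atol=1e-6)
    assert np.allclose(views.Rs_pooled.data,
                       views.Rs_tokens.data.mean(axis=0), atol=1e-6)
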
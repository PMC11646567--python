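"""RNA encoders: graph view (GAT over the contact graph) and sequence view
(multiscale 1-D CNN over averaged nucleotide + pretrained embeddings).

Graph view.  Nucleotides are embedded into R^d and updated by a multi-head
graph attention network over the contact graph.  For nucleotide i with
neighbourhood N(i), the attention logit against n in N(i) u {i} is
LeakyReLU(a^T [W_d h_i, W_d h_n]); the softmax over that support gives
coefficients alpha_in, and the update is ReLU(sum_n alpha_in W_a h_n).
Self-loops are added because the update references alpha_ii.  Head outputs
are averaged so the width stays d.

Sequence view.  Per position, the nucleotide embedding and a linear
projection of the pretrained embedding are averaged; three same-padded 1-D
convolution branches (kernel sizes 7, 11, 15) run over the result and are
averaged into E; the output is ReLU(W_c2 ReLU(W_c1 E)).  Zero padding keeps
every branch's output length equal to the input length p.

Both views are mean-pooled over nucleotides for their per-RNA vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._nn import Embedding, Linear, Module, glorot
from ._tensor import Tensor, conv1d_same, softmax_rows
from .featurization import ContactMap, RnaFeatures

NUM_NUCLEOTIDES = 4


@dataclass
class RnaViewEmbeddings:
    """Token and pooled embeddings for both RNA views (R^g, R^s)."""

    Rg_tokens: Tensor   # (p, d)
    Rg_pooled: Tensor   # (d,)
    Rs_tokens: Tensor   # (p, d)
    Rs_pooled: Tensor   # (d,)


class GatHead(Module):
    """One attention head: shared transform W_d, logit vector a, aggregation
    transform W_a."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W_d = Linear(d_in, d_out, rng, bias=False)
        self.a_src = glorot(rng, d_out, 1, shape=(d_out,))
        self.a_dst = glorot(rng, d_out, 1, shape=(d_out,))
        self.W_a = Linear(d_in, d_out, rng, bias=False)

    def attention(self, h: Tensor, contact: ContactMap,
                  leaky_slope: float) -> Tensor:
        """Row-stochastic (p, p) attention with support N(i) u {i}."""
        hd = self.W_d(h)                                   # (p, d_out)
        s_src = hd @ self.a_src.reshape(-1, 1)             # (p, 1)
        s_dst = hd @ self.a_dst.reshape(-1, 1)             # (p, 1)
        logits = (s_src + s_dst.T).leaky_relu(leaky_slope)  # (p, p)
        support = (contact.matrix + np.eye(contact.p, dtype=np.int64)) > 0
        return softmax_rows(logits, support)

    def aggregate(self, h: Tensor, attn: Tensor) -> Tensor:
        return (attn @ self.W_a(h)).relu()


class GatLayer(Module):
    """Multi-head GAT layer; head outputs averaged to keep width d."""

    def __init__(self, d_in: int, d_out: int, n_heads: int,
                 rng: np.random.Generator, leaky_slope: float = 0.2):
        super().__init__()
        self.leaky_slope = leaky_slope
        self.heads: List[GatHead] = []
        for i in range(n_heads):
            head = GatHead(d_in, d_out, rng)
            setattr(self, f"head{i}", head)
            self.heads.append(head)

    def __call__(self, h: Tensor, contact: ContactMap) -> Tensor:
        outs = [hd.aggregate(h, hd.attention(h, contact, self.leaky_slope))
                for hd in self.heads]
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        return acc / float(len(outs))


class GatEncoder(Module):
    """Nucleotide embedding + stacked GAT layers + mean pooling."""

    def __init__(self, d: int, n_layers: int = 2, n_heads: int = 4,
                 leaky_slope: float = 0.2,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.embedding = Embedding(NUM_NUCLEOTIDES, d, rng)
        self.layers: List[GatLayer] = []
        for i in range(n_layers):
            layer = GatLayer(d, d, n_heads, rng, leaky_slope)
            setattr(self, f"layer{i}", layer)
            self.layers.append(layer)

    def __call__(self, features: RnaFeatures) -> Tuple[Tensor, Tensor]:
        if features.contact.p != features.p:
            raise ValueError("contact map does not match sequence length")
        h = self.embedding(features.indices)
        for layer in self.layers:
            h = layer(h, features.contact)
        return h, h.mean(axis=0)


def gat_attention_coefficients(encoder: GatEncoder, node_states: Tensor,
                               contact: ContactMap, layer: int = 0,
                               head: int = 0) -> Tensor:
    """Attention matrix of one layer/head for given node states (testing and
    interpretability surface)."""
    gl = encoder.layers[layer]
    return gl.heads[head].attention(node_states, contact, gl.leaky_slope)


def gat_encode(features: RnaFeatures,
               encoder: GatEncoder) -> Tuple[Tensor, Tensor]:
    return encoder(features)


class MultiscaleCnnEncoder(Module):
    """Three same-padded conv branches over averaged inputs + projection head."""

    def __init__(self, d: int, d_pre: int,
                 kernel_sizes: Tuple[int, ...] = (7, 11, 15),
                 conv_bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if any(k % 2 == 0 for k in kernel_sizes):
            raise ValueError("kernel sizes must be odd to preserve length")
        self.kernel_sizes = tuple(kernel_sizes)
        self.embedding = Embedding(NUM_NUCLEOTIDES, d, rng)
        self.pre_proj = Linear(d_pre, d, rng)
        self.kernels: List[Tensor] = []
        self.biases: List[Optional[Tensor]] = []
        for i, k in enumerate(self.kernel_sizes):
            w = glorot(rng, k * d, d, shape=(k, d, d))
            setattr(self, f"kernel{i}", w)
            self.kernels.append(w)
            b = Tensor(np.zeros(d), requires_grad=True) if conv_bias else None
            if b is not None:
                setattr(self, f"bias{i}", b)
            self.biases.append(b)
        self.proj1 = Linear(d, d, rng)
        self.proj2 = Linear(d, d, rng)

    def input_signal(self, features: RnaFeatures) -> Tensor:
        """Position-wise average of nucleotide and projected pretrained
        embeddings."""
        nuc = self.embedding(features.indices)
        pre = self.pre_proj(Tensor(features.pretrained))
        return (nuc + pre) * 0.5

    def __call__(self, features: RnaFeatures) -> Tuple[Tensor, Tensor]:
        if features.p == 0:
            raise ValueError("empty RNA")
        x = self.input_signal(features)
        branches = [conv1d_same(x, w, b)
                    for w, b in zip(self.kernels, self.biases)]
        e = branches[0]
        for br in branches[1:]:
            e = e + br
        e = e / float(len(branches))
        rs = self.proj2(self.proj1(e).relu()).relu()
        return rs, rs.mean(axis=0)


def multiscale_cnn_encode(features: RnaFeatures,
                          encoder: MultiscaleCnnEncoder) -> Tuple[Tensor, Tensor]:
    return encoder(features)


class RnaEncoder(Module):
    """Both RNA views bundled; pooled vectors are row-means of the tokens."""

    def __init__(self, d: int, d_pre: int, n_gat_layers: int = 2,
                 n_gat_heads: int = 4, leaky_slope: float = 0.2,
                 kernel_sizes: Tuple[int, ...] = (7, 11, 15),
                 use_graph_view: bool = True, use_sequence_view: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if not (use_graph_view or use_sequence_view):
            raise ValueError("at least one view must be enabled")
        self.use_graph_view = use_graph_view
        self.use_sequence_view = use_sequence_view
        if use_graph_view:
            self.gat = GatEncoder(d, n_gat_layers, n_gat_heads, leaky_slope, rng)
        if use_sequence_view:
            self.cnn = MultiscaleCnnEncoder(d, d_pre, kernel_sizes, rng=rng)

    def __call__(self, features: RnaFeatures) -> RnaViewEmbeddings:
        rg_t = rg_p = rs_t = rs_p = None
        if self.use_graph_view:
            rg_t, rg_p = self.gat(features)
        if self.use_sequence_view:
            rs_t, rs_p = self.cnn(features)
        return RnaViewEmbeddings(rg_t, rg_p, rs_t, rs_p)
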
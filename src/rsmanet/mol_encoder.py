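"""Molecule encoders: graph view (GCN over the chemical graph) and sequence
view (Transformer over atomic-level SMILES tokens).

Graph view.  Standard symmetric-normalized graph convolution over the
self-connected adjacency: M^{g,l} = ReLU(D̃^{-1/2} Ã D̃^{-1/2} M^{g,l-1} W_e^l),
starting from the per-atom chemical feature matrix.

Sequence view.  SMILES tokens (atoms, bonds, ring digits, branches) are
embedded with learned positional embeddings and run through L Transformer
blocks (multi-head scaled dot-product self-attention, residual + layernorm,
position-wise FFN, residual + layernorm).  The atom mask then selects the q
heavy-atom rows, so the per-atom sequence embedding M^s has exactly q rows;
pooling averages atom rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._nn import Embedding, Linear, Module, TransformerBlock
from ._tensor import Tensor
from .featurization import (SMILES_VOCAB, MolGraph, TokenizedSMILES,
                            smiles_token_ids)

MAX_SMILES_TOKENS = 256


@dataclass
class MolViewEmbeddings:
    """Token and pooled embeddings for both molecule views (M^g, M^s)."""

    Mg_tokens: Tensor   # (q, d)
    Mg_pooled: Tensor   # (d,)
    Ms_tokens: Tensor   # (q, d)  atom positions only
    Ms_pooled: Tensor   # (d,)


class GcnEncoder(Module):
    """Stacked symmetric-normalized graph convolutions + mean pooling."""

    def __init__(self, d: int, f_atom: int, n_layers: int = 2,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.layers: List[Linear] = []
        dims = [f_atom] + [d] * n_layers
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            lin = Linear(a, b, rng, bias=False)
            setattr(self, f"W{i}", lin)
            self.layers.append(lin)

    def __call__(self, graph: MolGraph) -> Tuple[Tensor, Tensor]:
        norm_adj = Tensor(graph.normalized_adjacency())
        h = Tensor(graph.atom_feats)
        for lin in self.layers:
            h = (norm_adj @ lin(h)).relu()
        return h, h.mean(axis=0)


def gcn_encode(graph: MolGraph, encoder: GcnEncoder) -> Tuple[Tensor, Tensor]:
    return encoder(graph)


class SmilesTransformerEncoder(Module):
    """Token + positional embedding, L Transformer blocks, atom-row selection."""

    def __init__(self, d: int, n_blocks: int = 2, n_heads: int = 4,
                 max_len: int = MAX_SMILES_TOKENS,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.token_embedding = Embedding(len(SMILES_VOCAB), d, rng)
        self.pos_embedding = Embedding(max_len, d, rng)
        self.max_len = max_len
        self.blocks: List[TransformerBlock] = []
        for i in range(n_blocks):
            blk = TransformerBlock(d, n_heads, rng)
            setattr(self, f"block{i}", blk)
            self.blocks.append(blk)

    def __call__(self, tok: TokenizedSMILES,
                 key_mask: Optional[np.ndarray] = None
                 ) -> Tuple[Tensor, Tensor]:
        n = len(tok.tokens)
        if n == 0:
            raise ValueError(f"molecule {tok.mol_id!r}: empty token stream")
        if tok.q == 0:
            raise ValueError(f"molecule {tok.mol_id!r}: no atom tokens")
        if n > self.max_len:
            raise ValueError(f"molecule {tok.mol_id!r}: {n} tokens exceed "
                             f"max_len {self.max_len}")
        ids = smiles_token_ids(tok)
        h = self.token_embedding(ids) + self.pos_embedding(np.arange(n))
        for blk in self.blocks:
            h, _ = blk(h, key_mask)
        atom_idx = np.flatnonzero(tok.atom_mask)
        ms_tokens = h[atom_idx]
        return ms_tokens, ms_tokens.mean(axis=0)


def transformer_encode(tok: TokenizedSMILES,
                       encoder: SmilesTransformerEncoder
                       ) -> Tuple[Tensor, Tensor]:
    return encoder(tok)


class MolEncoder(Module):
    """Both molecule views bundled; pooled vectors are row-means of tokens."""

    def __init__(self, d: int, f_atom: int, n_gcn_layers: int = 2,
                 n_blocks: int = 2, n_heads: int = 4,
                 use_graph_view: bool = True, use_sequence_view: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if not (use_graph_view or use_sequence_view):
            raise ValueError("at least one view must be enabled")
        self.use_graph_view = use_graph_view
        self.use_sequence_view = use_sequence_view
        if use_graph_view:
            self.gcn = GcnEncoder(d, f_atom, n_gcn_layers, rng)
        if use_sequence_view:
            self.transformer = SmilesTransformerEncoder(
                d, n_blocks, n_heads, rng=rng)

    def __call__(self, graph: MolGraph,
                 tok: TokenizedSMILES) -> MolViewEmbeddings:
        mg_t = mg_p = ms_t = ms_p = None
        if self.use_graph_view:
            mg_t, mg_p = self.gcn(graph)
        if self.use_sequence_view:
            ms_t, ms_p = self.transformer(tok)
        return MolViewEmbeddings(mg_t, mg_p, ms_t, ms_p)
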
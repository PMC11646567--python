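"""Cross-fusion module: segment embeddings + parallel multi-head
cross-attention Transformer blocks between RNA nucleotides and molecule
atoms across graph and sequence views.

The RNA input stacks the graph-view and sequence-view token matrices with a
learned segment embedding added to each view: R^c = [R^g + S^g; R^s + S^s]
(2p x d), and likewise M^c (2q x d) for the molecule.  Each block runs two
perspectives in parallel from the block's inputs: the RNA perspective takes
queries from R^c and keys/values from M^c (score shape 2p x 2q), the
molecule perspective the reverse (2q x 2p).  Each perspective then applies
head concatenation, residual + layernorm, a position-wise FFN, and a second
residual + layernorm, exactly as a Transformer block with the self-attention
swapped for cross-attention.  After L blocks the segment-wise means give
R̄^{c,g}, R̄^{c,s}, M̄^{c,g}, M̄^{c,s}; the post-softmax score matrices of
every block and head are retained for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._nn import (FeedForward, LayerNorm, Module, MultiHeadAttention)
from ._tensor import Tensor, concat
from .mol_encoder import MolViewEmbeddings
from .rna_encoder import RnaViewEmbeddings


class SegmentEmbeddings(Module):
    """Learned graph-view (S^g) and sequence-view (S^s) segment vectors,
    shared between the RNA and molecule inputs."""

    def __init__(self, d: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.S_g = Tensor(rng.normal(0.0, 0.02, size=(d,)), requires_grad=True)
        self.S_s = Tensor(rng.normal(0.0, 0.02, size=(d,)), requires_grad=True)


@dataclass
class CrossInputs:
    """Stacked view tokens with segment embeddings added.

    `rna_segments` / `mol_segments` give each view's row count in stacking
    order, so segment-wise pooling and the score-matrix block structure
    ([gg, gs; sg, ss]) can be recovered.
    """

    R_c: Tensor                 # (sum(rna_segments), d)
    M_c: Tensor                 # (sum(mol_segments), d)
    rna_segments: Tuple[int, ...]
    mol_segments: Tuple[int, ...]


def apply_segment_embeddings(rna: RnaViewEmbeddings, mol: MolViewEmbeddings,
                             seg: SegmentEmbeddings) -> CrossInputs:
    """Build R^c = [R^g + S^g; R^s + S^s] and M^c = [M^g + S^g; M^s + S^s].

    Disabled views (ablations) simply drop out of the stack.
    """
    r_parts, r_lens = [], []
    if rna.Rg_tokens is not None:
        r_parts.append(rna.Rg_tokens + seg.S_g)
        r_lens.append(rna.Rg_tokens.shape[0])
    if rna.Rs_tokens is not None:
        r_parts.append(rna.Rs_tokens + seg.S_s)
        r_lens.append(rna.Rs_tokens.shape[0])
    m_parts, m_lens = [], []
    if mol.Mg_tokens is not None:
        m_parts.append(mol.Mg_tokens + seg.S_g)
        m_lens.append(mol.Mg_tokens.shape[0])
    if mol.Ms_tokens is not None:
        m_parts.append(mol.Ms_tokens + seg.S_s)
        m_lens.append(mol.Ms_tokens.shape[0])
    if not r_parts or not m_parts:
        raise ValueError("cross-fusion needs at least one view per entity")
    r_c = r_parts[0] if len(r_parts) == 1 else concat(r_parts, axis=0)
    m_c = m_parts[0] if len(m_parts) == 1 else concat(m_parts, axis=0)
    return CrossInputs(r_c, m_c, tuple(r_lens), tuple(m_lens))


@dataclass
class AttentionMaps:
    """Post-softmax cross-attention scores per block and head.

    rna_perspective[b][h] is (2p, 2q) (queries are RNA rows); mol_perspective
    [b][h] is (2q, 2p).  With single-view ablations the factors of 2 drop.
    """

    rna_perspective: List[List[np.ndarray]] = field(default_factory=list)
    mol_perspective: List[List[np.ndarray]] = field(default_factory=list)
    rna_segments: Tuple[int, ...] = ()
    mol_segments: Tuple[int, ...] = ()


class CrossAttentionBlock(Module):
    """One cross-fusion Transformer block with two parallel perspectives."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 ffn_mult: int = 2):
        super().__init__()
        self.attn_rna = MultiHeadAttention(d, n_heads, rng)
        self.attn_mol = MultiHeadAttention(d, n_heads, rng)
        self.ln1_rna = LayerNorm(d)
        self.ln1_mol = LayerNorm(d)
        self.ffn_rna = FeedForward(d, ffn_mult * d, rng)
        self.ffn_mol = FeedForward(d, ffn_mult * d, rng)
        self.ln2_rna = LayerNorm(d)
        self.ln2_mol = LayerNorm(d)

    def __call__(self, r_c: Tensor, m_c: Tensor,
                 rna_key_mask: Optional[np.ndarray] = None,
                 mol_key_mask: Optional[np.ndarray] = None):
        # both perspectives read the block's INPUTS (parallel update)
        a_r, scores_r = self.attn_rna(r_c, m_c, mol_key_mask)
        a_m, scores_m = self.attn_mol(m_c, r_c, rna_key_mask)
        h_r = self.ln1_rna(r_c + a_r)
        h_m = self.ln1_mol(m_c + a_m)
        out_r = self.ln2_rna(h_r + self.ffn_rna(h_r))
        out_m = self.ln2_mol(h_m + self.ffn_mol(h_m))
        return out_r, out_m, scores_r, scores_m


def cross_attention_block(r_c: Tensor, m_c: Tensor,
                          block: CrossAttentionBlock):
    return block(r_c, m_c)


@dataclass
class CrossFusionOutput:
    """Segment-wise pooled cross embeddings plus retained attention maps."""

    R_cg: Optional[Tensor]   # (d,)
    R_cs: Optional[Tensor]
    M_cg: Optional[Tensor]
    M_cs: Optional[Tensor]
    attention: AttentionMaps


def _segment_means(tokens: Tensor, segments: Tuple[int, ...]) -> List[Tensor]:
    means, lo = [], 0
    for n in segments:
        means.append(tokens[lo:lo + n].mean(axis=0))
        lo += n
    return means


class CrossFusionEncoder(Module):
    """Segment embeddings + L parallel cross-attention blocks + pooling."""

    def __init__(self, d: int, n_blocks: int = 1, n_heads: int = 4,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.segments = SegmentEmbeddings(d, rng)
        self.blocks: List[CrossAttentionBlock] = []
        for i in range(n_blocks):
            blk = CrossAttentionBlock(d, n_heads, rng)
            setattr(self, f"block{i}", blk)
            self.blocks.append(blk)

    def __call__(self, rna: RnaViewEmbeddings,
                 mol: MolViewEmbeddings) -> CrossFusionOutput:
        inp = apply_segment_embeddings(rna, mol, self.segments)
        r_c, m_c = inp.R_c, inp.M_c
        maps = AttentionMaps(rna_segments=inp.rna_segments,
                             mol_segments=inp.mol_segments)
        for blk in self.blocks:
            r_c, m_c, s_r, s_m = blk(r_c, m_c)
            maps.rna_perspective.append(s_r)
            maps.mol_perspective.append(s_m)
        r_means = _segment_means(r_c, inp.rna_segments)
        m_means = _segment_means(m_c, inp.mol_segments)
        # map pooled segments back to (graph, sequence) slots
        r_iter = iter(r_means)
        m_iter = iter(m_means)
        r_cg = next(r_iter) if rna.Rg_tokens is not None else None
        r_cs = next(r_iter) if rna.Rs_tokens is not None else None
        m_cg = next(m_iter) if mol.Mg_tokens is not None else None
        m_cs = next(m_iter) if mol.Ms_tokens is not None else None
        return CrossFusionOutput(r_cg, r_cs, m_cg, m_cs, maps)


def cross_fusion_encode(rna: RnaViewEmbeddings, mol: MolViewEmbeddings,
                        encoder: CrossFusionEncoder) -> CrossFusionOutput:
    return encoder(rna, mol)
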
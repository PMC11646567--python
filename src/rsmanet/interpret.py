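"""Attention interpretability: collapse cross-fusion attention maps into
per-nucleotide and per-atom importance scores and top-k rankings.

The RNA-perspective score matrix of each block/head is (2p, 2q): query rows
0..p-1 are graph-view nucleotides, rows p..2p-1 sequence-view nucleotides.
The importance of nucleotide j is the flat mean, over blocks, heads, and
key positions, of its graph-view and sequence-view query rows — i.e. the
two view perspectives are averaged into one score.  Atom scores come from
the molecule perspective the same way.  Rankings sort by descending score
with ties broken by ascending position index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np

from .cross_fusion import AttentionMaps


@dataclass
class AttentionRanking:
    rna_id: str
    mol_id: str
    nucleotide_scores: np.ndarray          # (p,)
    atom_scores: np.ndarray                # (q,)
    top_nucleotides: Dict[int, List[int]] = field(default_factory=dict)
    top_atoms: Dict[int, List[int]] = field(default_factory=dict)


def _collapse(per_block_heads: List[List[np.ndarray]],
              segments: Sequence[int]) -> np.ndarray:
    """Average score matrices over blocks, heads, keys, and view segments."""
    n_pos = segments[0]
    if any(s != n_pos for s in segments):
        raise ValueError("view segments disagree on entity length")
    acc = np.zeros(n_pos)
    count = 0
    for heads in per_block_heads:
        for mat in heads:
            if mat.shape[0] != sum(segments):
                raise ValueError(
                    f"score matrix rows {mat.shape[0]} != "
                    f"sum of segments {sum(segments)}")
            row_means = mat.mean(axis=1)       # mean over keys
            lo = 0
            for s in segments:
                acc += row_means[lo:lo + s]
                count += 1
                lo += s
    if count == 0:
        raise ValueError("no attention maps retained (was fusion enabled?)")
    return acc / count


def _top_k(scores: np.ndarray, k: int) -> List[int]:
    # descending score, ascending index on ties
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:min(k, len(scores))].tolist()


def extract_attention_ranking(maps: AttentionMaps, p: int, q: int,
                              rna_id: str = "?", mol_id: str = "?",
                              k_list: Sequence[int] = (5, 10)
                              ) -> AttentionRanking:
    """Per-nucleotide and per-atom importance from one forward pass."""
    if maps.rna_segments and sum(maps.rna_segments) != len(maps.rna_segments) * p:
        raise ValueError(f"maps were produced for p={maps.rna_segments[0]}, "
                         f"not p={p}")
    if maps.mol_segments and sum(maps.mol_segments) != len(maps.mol_segments) * q:
        raise ValueError(f"maps were produced for q={maps.mol_segments[0]}, "
                         f"not q={q}")
    nuc = _collapse(maps.rna_perspective, maps.rna_segments or (p,))
    atom = _collapse(maps.mol_perspective, maps.mol_segments or (q,))
    ranking = AttentionRanking(rna_id, mol_id, nuc, atom)
    for k in k_list:
        ranking.top_nucleotides[k] = _top_k(nuc, k)
        ranking.top_atoms[k] = _top_k(atom, k)
    return ranking


def ranking_to_json(ranking: AttentionRanking,
                    path: Union[str, Path, None] = None) -> str:
    """JSON export; positions are also given 1-based for structure viewers."""
    payload = {
        "rna_id": ranking.rna_id,
        "mol_id": ranking.mol_id,
        "nucleotide_scores": ranking.nucleotide_scores.tolist(),
        "atom_scores": ranking.atom_scores.tolist(),
        "top_nucleotides": {str(k): v
                            for k, v in ranking.top_nucleotides.items()},
        "top_atoms": {str(k): v for k, v in ranking.top_atoms.items()},
        "top_nucleotides_1based": {
            str(k): [i + 1 for i in v]
            for k, v in ranking.top_nucleotides.items()},
        "top_atoms_1based": {str(k): [i + 1 for i in v]
                             for k, v in ranking.top_atoms.items()},
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def ranking_to_tsv(ranking: AttentionRanking, tokens_rna: Sequence[str],
                   tokens_mol: Sequence[str],
                   path: Union[str, Path, None] = None) -> str:
    """Flat TSV (entity, position_1based, token, score, rank) for plotting."""
    lines = ["entity\tposition\ttoken\tscore\trank"]
    for name, scores, toks in (("rna", ranking.nucleotide_scores, tokens_rna),
                               ("mol", ranking.atom_scores, tokens_mol)):
        order = _top_k(scores, len(scores))
        rank_of = {pos: r + 1 for r, pos in enumerate(order)}
        for i, s in enumerate(scores):
            tok = tokens_rna[i] if name == "rna" else tokens_mol[i]
            lines.append(f"{name}\t{i + 1}\t{tok}\t{s:.8g}\t{rank_of[i]}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
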
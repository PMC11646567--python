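"""Model-ready features for RNAs and small molecules.

RNA side: integer nucleotide indices, a binary symmetric contact map (the
graph of nucleotide pairs whose nearest heavy atoms fall within an 8 Å
cutoff, supplied by an external secondary-structure predictor or a seeded
synthetic stand-in), and a per-nucleotide pretrained-language-model
embedding obtained through a pluggable provider.

Molecule side: the heavy-atom chemical graph with self-connected adjacency
Ã and its degree matrix D̃ plus per-atom feature vectors, and an
atomic-level SMILES tokenization whose atom mask ties Transformer token
positions back to the q heavy atoms of the parsed molecule.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Protocol, Union

import numpy as np
from rdkit import Chem

from .data_io import MoleculeRecord, RNARecord, ValidationError

NUCLEOTIDE_VOCAB: Dict[str, int] = {"A": 0, "C": 1, "G": 2, "U": 3}

MAX_RNA_LENGTH = 512  # longer sequences are rejected, never silently truncated


# --------------------------------------------------------------------------
# RNA features
# --------------------------------------------------------------------------

def encode_rna_tokens(rna: RNARecord) -> np.ndarray:
    """Map a normalized A/C/G/U sequence to integer indices (A0 C1 G2 U3)."""
    try:
        return np.array([NUCLEOTIDE_VOCAB[c] for c in rna.sequence],
                        dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(
            f"RNA {rna.id!r}: unknown nucleotide {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class ContactMap:
    """Binary symmetric p x p nucleotide contact matrix."""

    rna_id: str
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"contact map for {self.rna_id!r}: not square")
        if not np.array_equal(m, m.T):
            raise ValidationError(f"contact map for {self.rna_id!r}: asymmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError(
                f"contact map for {self.rna_id!r}: entries must be 0/1")

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def synthetic_contact_map(rna: RNARecord, seed: int,
                          density: float = 0.05) -> ContactMap:
    """Backbone-chain contacts (|i-j| == 1) plus seeded random symmetric
    long-range contacts at roughly the given density."""
    p = rna.p
    m = np.zeros((p, p), dtype=np.int64)
    idx = np.arange(p - 1)
    m[idx, idx + 1] = 1
    m[idx + 1, idx] = 1
    if p > 2 and density > 0:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(p, k=2)
        hits = rng.random(iu.size) < density
        m[iu[hits], ju[hits]] = 1
        m[ju[hits], iu[hits]] = 1
    return ContactMap(rna.id, m)


def load_contact_map(rna: RNARecord, path: Union[str, Path]) -> ContactMap:
    """Load a whitespace-delimited p x p 0/1 matrix file for one RNA."""
    mat = np.loadtxt(Path(path), ndmin=2)
    if mat.shape != (rna.p, rna.p):
        raise ValidationError(
            f"contact map for {rna.id!r}: file shape {mat.shape} "
            f"!= ({rna.p}, {rna.p})")
    return ContactMap(rna.id, mat.astype(np.int64))


def load_or_make_contact_map(rna: RNARecord,
                             source: Union[str, Path] = "synthetic",
                             seed: int = 0,
                             density: float = 0.05) -> ContactMap:
    if isinstance(source, str) and source == "synthetic":
        return synthetic_contact_map(rna, seed=seed, density=density)
    return load_contact_map(rna, source)


class EmbeddingProvider(Protocol):
    """Per-nucleotide pretrained embedding source (p x d_pre, deterministic)."""

    name: str
    d_pre: int

    def __call__(self, rna: RNARecord) -> np.ndarray: ...


class MockEmbeddingProvider:
    """Deterministic stand-in for a pretrained RNA language model.

    Synthetic: each row is drawn from a PCG64 stream keyed by a BLAKE2b hash
    of (provider seed, sequence, position), so the matrix is bit-reproducible
    across processes and platforms while varying with sequence context.
    """

    def __init__(self, d_pre: int = 16, seed: int = 0):
        self.name = f"mock-{d_pre}-{seed}"
        self.d_pre = d_pre
        self.seed = seed

    def __call__(self, rna: RNARecord) -> np.ndarray:
        rows = np.empty((rna.p, self.d_pre))
        for i in range(rna.p):
            key = f"{self.seed}|{rna.sequence}|{i}".encode()
            digest = hashlib.blake2b(key, digest_size=8).digest()
            stream = np.random.default_rng(int.from_bytes(digest, "little"))
            rows[i] = stream.standard_normal(self.d_pre)
        return rows


class FileEmbeddingProvider:
    """Load precomputed per-RNA embedding matrices (<rna_id>.txt, p rows)."""

    def __init__(self, directory: Union[str, Path], d_pre: int,
                 name: str = "file"):
        self.directory = Path(directory)
        self.d_pre = d_pre
        self.name = name

    def __call__(self, rna: RNARecord) -> np.ndarray:
        path = self.directory / f"{rna.id}.txt"
        if not path.exists():
            raise KeyError(f"no embedding file for RNA {rna.id!r} at {path}")
        mat = np.loadtxt(path, ndmin=2)
        if mat.shape != (rna.p, self.d_pre):
            raise ValidationError(
                f"embedding for {rna.id!r}: shape {mat.shape} != "
                f"({rna.p}, {self.d_pre})")
        return mat


def get_pretrained_embedding(rna: RNARecord,
                             provider: EmbeddingProvider) -> np.ndarray:
    mat = provider(rna)
    if mat.shape[0] != rna.p:
        raise ValidationError(
            f"provider {provider.name!r} returned {mat.shape[0]} rows for "
            f"RNA {rna.id!r} of length {rna.p}")
    return mat


@dataclass(frozen=True)
class RnaFeatures:
    """Everything the RNA encoders consume for one RNA."""

    rna_id: str
    indices: np.ndarray          # (p,) int over {A,C,G,U}
    contact: ContactMap          # p x p
    pretrained: np.ndarray       # p x d_pre

    def __post_init__(self):
        p = self.indices.shape[0]
        if self.contact.p != p or self.pretrained.shape[0] != p:
            raise ValidationError(
                f"RNA {self.rna_id!r}: component length mismatch "
                f"(indices {p}, contact {self.contact.p}, "
                f"pretrained {self.pretrained.shape[0]})")

    @property
    def p(self) -> int:
        return self.indices.shape[0]


def featurize_rna(rna: RNARecord,
                  provider: EmbeddingProvider,
                  contact_source: Union[str, Path] = "synthetic",
                  contact_seed: int = 0,
                  contact_density: float = 0.05) -> RnaFeatures:
    if rna.p > MAX_RNA_LENGTH:
        raise ValidationError(
            f"RNA {rna.id!r}: length {rna.p} exceeds the maximum "
            f"{MAX_RNA_LENGTH}")
    return RnaFeatures(
        rna_id=rna.id,
        indices=encode_rna_tokens(rna),
        contact=load_or_make_contact_map(rna, contact_source, contact_seed,
                                         contact_density),
        pretrained=get_pretrained_embedding(rna, provider),
    )


# --------------------------------------------------------------------------
# Molecule features
# --------------------------------------------------------------------------

# Atom feature layout (heavy atoms; hydrogens implicit):
#   element one-hot over ELEMENTS + other        10
#   degree one-hot 0..5                           6
#   formal charge                                 1
#   number of radical electrons                   1
#   hybridization one-hot over HYBRIDIZATIONS+    6
#   aromaticity flag                              1
#   total hydrogen count one-hot 0..4             5
ELEMENTS = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")
HYBRIDIZATIONS = (
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
)
ATOM_FEATURE_DIM = (len(ELEMENTS) + 1) + 6 + 1 + 1 + (len(HYBRIDIZATIONS) + 1) + 1 + 5


def _one_hot(value, choices) -> list:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = (
        _one_hot(atom.GetSymbol(), ELEMENTS)
        + _one_hot(min(atom.GetDegree(), 5), (0, 1, 2, 3, 4, 5))[:-1]
        + [float(atom.GetFormalCharge()),
           float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(min(atom.GetTotalNumHs(), 4), (0, 1, 2, 3, 4))[:-1]
    )
    return np.array(feats, dtype=np.float64)


@dataclass(frozen=True)
class MolGraph:
    """Heavy-atom chemical graph: self-connected adjacency Ã, degree D̃,
    and the q x f atom feature matrix."""

    mol_id: str
    A_tilde: np.ndarray       # (q, q) binary, diag == 1, symmetric
    atom_feats: np.ndarray    # (q, f)

    def __post_init__(self):
        a = self.A_tilde
        if not np.array_equal(a, a.T):
            raise ValidationError(f"molecule {self.mol_id!r}: Ã asymmetric")
        if not np.array_equal(np.diag(a), np.ones(a.shape[0])):
            raise ValidationError(
                f"molecule {self.mol_id!r}: Ã diagonal must be all ones")

    @property
    def q(self) -> int:
        return self.A_tilde.shape[0]

    @property
    def D_tilde(self) -> np.ndarray:
        return np.diag(self.A_tilde.sum(axis=1))

    def normalized_adjacency(self) -> np.ndarray:
        """Symmetric normalization D̃^{-1/2} Ã D̃^{-1/2}."""
        d_inv_sqrt = 1.0 / np.sqrt(self.A_tilde.sum(axis=1))
        return self.A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def build_mol_graph(mol_rec: MoleculeRecord) -> MolGraph:
    mol = mol_rec.mol()
    if mol is None:
        raise ValidationError(f"molecule {mol_rec.id!r}: unparsable SMILES")
    q = mol.GetNumAtoms()
    a = np.eye(q, dtype=np.int64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        a[i, j] = a[j, i] = 1
    feats = np.stack([atom_features(atom) for atom in mol.GetAtoms()])
    return MolGraph(mol_rec.id, a, feats)


# Atomic-level SMILES tokenization: bracket atoms are one token, two-letter
# elements (Cl, Br) are one token, then single-character atoms, bonds, ring
# digits (incl. %nn), branches and stereo marks.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|b|c|n|o|s|p|B|C|N|O|S|P|F|I"
    r"|%\d{2}|\d|\(|\)|=|#|-|\+|\\|/|:|~|@|\*|\.|\$)"
)
_ATOM_TOKEN_RE = re.compile(r"^(\[[^\]]+\]|Br|Cl|b|c|n|o|s|p|B|C|N|O|S|P|F|I)$")


@dataclass(frozen=True)
class TokenizedSMILES:
    """Atomic-level token stream plus the mask selecting heavy-atom tokens."""

    mol_id: str
    tokens: tuple
    atom_mask: np.ndarray    # bool, len(tokens)

    @property
    def q(self) -> int:
        return int(self.atom_mask.sum())


def tokenize_smiles(mol_rec: MoleculeRecord) -> TokenizedSMILES:
    smiles = mol_rec.smiles
    tokens = SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValidationError(
            f"molecule {mol_rec.id!r}: tokenizer could not consume "
            f"{smiles!r} fully")
    mask = np.array([bool(_ATOM_TOKEN_RE.match(t)) for t in tokens])
    q_tok = int(mask.sum())
    q_parsed = mol_rec.q
    if q_tok != q_parsed:
        raise ValidationError(
            f"molecule {mol_rec.id!r}: {q_tok} atom tokens but parser "
            f"reports {q_parsed} heavy atoms")
    return TokenizedSMILES(mol_rec.id, tuple(tokens), mask)


# Fixed Transformer token vocabulary covering the tokenizer's output classes;
# anything else (rare bracket atoms) maps to <unk>.
SMILES_VOCAB: Dict[str, int] = {
    tok: i for i, tok in enumerate(
        ["<unk>", "B", "C", "N", "O", "S", "P", "F", "I", "Cl", "Br",
         "b", "c", "n", "o", "s", "p",
         "[nH]", "[NH+]", "[NH2+]", "[NH3+]", "[N+]", "[N-]", "[O-]", "[OH+]",
         "[S-]", "[s+]", "[n+]", "[C@H]", "[C@@H]", "[C@]", "[C@@]",
         "0", "1", "2", "3", "4", "5", "6", "7", "8", "9",
         "(", ")", "=", "#", "-", "+", "\\", "/", ":", "~", "@", "*", ".",
         "$", "%10", "%11", "%12"]
    )
}


def smiles_token_ids(tok: TokenizedSMILES) -> np.ndarray:
    unk = SMILES_VOCAB["<unk>"]
    return np.array([SMILES_VOCAB.get(t, unk) for t in tok.tokens],
                    dtype=np.int64)


@dataclass(frozen=True)
class MolFeatures:
    """Everything the molecule encoders consume for one molecule."""

    mol_id: str
    graph: MolGraph
    tokens: TokenizedSMILES

    @property
    def q(self) -> int:
        return self.graph.q


def featurize_molecule(mol_rec: MoleculeRecord) -> MolFeatures:
    return MolFeatures(mol_rec.id, build_mol_graph(mol_rec),
                       tokenize_smiles(mol_rec))
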
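"""Dataset I/O: pair tables, RNA FASTA, SMILES files, prediction output.

The pair table is the source of truth: every (rna_id, mol_id) pair must
resolve to a loaded RNA sequence and molecule, while orphan records (an RNA
or molecule never referenced by any pair) are allowed and logged.  Affinity
values are taken as pKd — the negative base-10 logarithm of the dissociation
constant in molar — with no unit conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise; our own errors carry the ids

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


class ValidationError(ValueError):
    """A record failed validation; the message names the offending id(s)."""


@dataclass(frozen=True)
class RNARecord:
    """One RNA: identifier and its normalized A/C/G/U sequence of length p."""

    id: str
    sequence: str

    @property
    def p(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"RNA {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"RNA {self.id!r}: non-ACGU characters {sorted(bad)}")


@dataclass(frozen=True)
class MoleculeRecord:
    """One small molecule: identifier and SMILES with q heavy atoms."""

    id: str
    smiles: str

    def __post_init__(self):
        if self.mol() is None:
            raise ValidationError(f"molecule {self.id!r}: unparsable SMILES "
                                  f"{self.smiles!r}")

    def mol(self) -> Optional[Chem.Mol]:
        return Chem.MolFromSmiles(self.smiles)

    @property
    def q(self) -> int:
        return self.mol().GetNumAtoms()


@dataclass(frozen=True)
class AffinityPair:
    """One (RNA, molecule, pKd) measurement."""

    rna_id: str
    mol_id: str
    affinity: float

    def __post_init__(self):
        if not np.isfinite(self.affinity):
            raise ValidationError(
                f"pair ({self.rna_id}, {self.mol_id}): non-finite affinity")


@dataclass
class Dataset:
    """RNA and molecule tables plus the affinity pair list referencing them."""

    rnas: Dict[str, RNARecord] = field(default_factory=dict)
    molecules: Dict[str, MoleculeRecord] = field(default_factory=dict)
    pairs: List[AffinityPair] = field(default_factory=list)

    def validate(self) -> "Dataset":
        if not self.pairs:
            raise ValidationError("no pairs")
        seen = set()
        for pr in self.pairs:
            if pr.rna_id not in self.rnas:
                raise ValidationError(f"pair references unknown RNA {pr.rna_id!r}")
            if pr.mol_id not in self.molecules:
                raise ValidationError(
                    f"pair references unknown molecule {pr.mol_id!r}")
            key = (pr.rna_id, pr.mol_id)
            if key in seen:
                raise ValidationError(f"duplicate pair {key}")
            seen.add(key)
        used_r = {p.rna_id for p in self.pairs}
        used_m = {p.mol_id for p in self.pairs}
        for rid in set(self.rnas) - used_r:
            logger.info("orphan RNA record %r (no pair references it)", rid)
        for mid in set(self.molecules) - used_m:
            logger.info("orphan molecule record %r (no pair references it)", mid)
        return self

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """New Dataset sharing record tables, restricted to `indices` pairs."""
        sub = Dataset(rnas=self.rnas, molecules=self.molecules,
                      pairs=[self.pairs[i] for i in indices])
        return sub.validate()

    @property
    def affinities(self) -> np.ndarray:
        return np.array([p.affinity for p in self.pairs], dtype=float)


def normalize_rna_sequence(seq: str, rna_id: str = "?") -> str:
    """Uppercase and map DNA T to U (mixed-alphabet sources are common)."""
    up = seq.strip().upper()
    if "T" in up:
        logger.warning("RNA %r: DNA letter T normalized to U", rna_id)
        up = up.replace("T", "U")
    return up


def read_fasta(path: Union[str, Path]) -> Dict[str, RNARecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: Dict[str, RNARecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = RNARecord(rec.id,
                                    normalize_rna_sequence(str(rec.seq), rec.id))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def read_smiles(path: Union[str, Path]) -> Dict[str, MoleculeRecord]:
    """Read molecules from a .smi file (``SMILES<ws>id`` per line) or a CSV
    with columns ``mol_id, smiles``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: List[tuple] = []
    if path.suffix.lower() in {".csv", ".tsv"}:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        if not {"mol_id", "smiles"} <= set(df.columns):
            raise ValidationError(f"{path}: need columns mol_id, smiles")
        entries = list(zip(df["mol_id"].astype(str), df["smiles"].astype(str)))
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}: .smi line needs 'SMILES id': "
                                      f"{line!r}")
            entries.append((parts[1], parts[0]))
    mols: Dict[str, MoleculeRecord] = {}
    bad: List[str] = []
    for mid, smi in entries:
        if mid in mols:
            raise ValidationError(f"duplicate molecule id {mid!r}")
        try:
            mols[mid] = MoleculeRecord(mid, smi)
        except ValidationError:
            bad.append(mid)
    if bad:
        raise ValidationError(f"unparsable SMILES for ids: {bad}")
    if not mols:
        raise ValidationError(f"no molecules in {path}")
    return mols


def read_pair_table(path: Union[str, Path]) -> List[AffinityPair]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    needed = {"rna_id", "mol_id", "affinity"}
    if not needed <= set(df.columns):
        raise ValidationError(f"{path}: pair table needs columns {sorted(needed)}")
    return [AffinityPair(str(r.rna_id), str(r.mol_id), float(r.affinity))
            for r in df.itertuples()]


def load_dataset(pairs_path: Union[str, Path], fasta_path: Union[str, Path],
                 smiles_path: Union[str, Path]) -> Dataset:
    """Load and validate a full dataset from its three files."""
    ds = Dataset(rnas=read_fasta(fasta_path),
                 molecules=read_smiles(smiles_path),
                 pairs=read_pair_table(pairs_path))
    return ds.validate()


def write_predictions(pairs: Sequence[AffinityPair], scores: Sequence[float],
                      path: Union[str, Path],
                      include_true: bool = True) -> None:
    """Write a predictions CSV aligned row-for-row with `pairs`."""
    if len(pairs) != len(scores):
        raise ValueError(f"{len(pairs)} pairs but {len(scores)} scores")
    cols = {"rna_id": [p.rna_id for p in pairs],
            "mol_id": [p.mol_id for p in pairs]}
    if include_true:
        cols["affinity_true"] = [p.affinity for p in pairs]
    cols["affinity_pred"] = [float(s) for s in scores]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def write_dataset(ds: Dataset, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write a dataset to `out_dir` as pairs.csv / rnas.fasta / mols.smi."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"pairs": out / "pairs.csv", "fasta": out / "rnas.fasta",
             "smiles": out / "mols.smi"}
    pd.DataFrame({"rna_id": [p.rna_id for p in ds.pairs],
                  "mol_id": [p.mol_id for p in ds.pairs],
                  "affinity": [p.affinity for p in ds.pairs]}
                 ).to_csv(paths["pairs"], index=False)
    with open(paths["fasta"], "w") as fh:
        for rec in ds.rnas.values():
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    with open(paths["smiles"], "w") as fh:
        for rec in ds.molecules.values():
            fh.write(f"{rec.smiles} {rec.id}\n")
    return paths
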
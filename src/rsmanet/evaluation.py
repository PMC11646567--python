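"""Evaluation harness: stratified and blind cross-validation splits,
regression and classification metrics, molecular/sequence similarity, and
independent-test leakage filtering.

Regression metrics are Pearson and Spearman correlation and RMSE in pKd
units.  For the companion classification view, pairs with true pKd at or
above a threshold (default 4.0) count as binders; specificity and balanced
accuracy threshold the predictions the same way, while AUC ranks the raw
predicted scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data_io import Dataset, MoleculeRecord
from .model import (AffinityModel, AffinityModelConfig, FeatureStore,
                    Providers, predict_batch, train)

logger = logging.getLogger(__name__)

CLASSIFICATION_THRESHOLD = 4.0   # pKd cut separating binders from non-binders

SPLIT_MODES = ("stratified_kfold", "blind_rna", "blind_mol", "all_blind")


@dataclass
class SplitPlan:
    """Fold assignment per pair index; -1 marks pairs excluded by the mode
    (possible only under all_blind)."""

    mode: str
    k: int
    assignment: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def to_csv(self, path) -> None:
        pd.DataFrame({"pair_index": np.arange(len(self.assignment)),
                      "fold": self.assignment}).to_csv(path, index=False)


def _entity_partition(ids: List[str], k: int,
                      rng: np.random.Generator) -> Dict[str, int]:
    if len(ids) < k:
        raise ValueError(f"{len(ids)} entities cannot fill {k} blind folds")
    ids = sorted(ids)
    rng.shuffle(ids)
    return {eid: i % k for i, eid in enumerate(ids)}


def make_splits(dataset: Dataset, mode: str, k: int, seed: int) -> SplitPlan:
    """Build a cross-validation plan.

    stratified_kfold bins affinities into 10 quantile bins and deals each
    bin round-robin across folds so every fold tracks the global affinity
    distribution.  Blind modes partition entity ids and let pairs follow
    their entity; all_blind partitions both id sets and keeps only pairs
    whose RNA and molecule land in the same fold.
    """
    if mode not in SPLIT_MODES:
        raise ValueError(f"unknown split mode {mode!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(dataset.pairs)
    assignment = np.full(n, -1, dtype=np.int64)
    if mode == "stratified_kfold":
        y = dataset.affinities
        n_bins = min(10, n)
        # quantile bin edges; ranks avoid degenerate edges under ties
        ranks = stats.rankdata(y, method="ordinal") - 1
        bins = (ranks * n_bins // n).astype(int)
        fold_cursor = 0
        for b in np.unique(bins):
            members = np.flatnonzero(bins == b)
            rng.shuffle(members)
            for m in members:
                assignment[m] = fold_cursor % k
                fold_cursor += 1
    elif mode in ("blind_rna", "blind_mol"):
        key = "rna_id" if mode == "blind_rna" else "mol_id"
        ids = sorted({getattr(p, key) for p in dataset.pairs})
        part = _entity_partition(ids, k, rng)
        for i, p in enumerate(dataset.pairs):
            assignment[i] = part[getattr(p, key)]
    else:  # all_blind
        rna_part = _entity_partition(
            sorted({p.rna_id for p in dataset.pairs}), k, rng)
        mol_part = _entity_partition(
            sorted({p.mol_id for p in dataset.pairs}), k, rng)
        for i, p in enumerate(dataset.pairs):
            if rna_part[p.rna_id] == mol_part[p.mol_id]:
                assignment[i] = rna_part[p.rna_id]
    if mode != "all_blind" and (assignment < 0).any():
        raise AssertionError("folds must partition the pairs")
    return SplitPlan(mode, k, assignment, seed)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    pcc: float
    scc: float
    rmse: float
    specificity: Optional[float] = None
    bacc: Optional[float] = None
    auc: Optional[float] = None
    n: int = 0

    def to_dict(self) -> Dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]
                       ) -> Tuple[float, float, float]:
    """Pearson r, Spearman rho (average ranks on ties), RMSE."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(yt) == 0:
        raise ValueError("correlation undefined for constant y_true")
    pcc = float(stats.pearsonr(yt, yp).statistic)
    scc = float(stats.spearmanr(yt, yp).statistic)
    rmse = float(np.sqrt(np.mean((yt - yp) ** 2)))
    return pcc, scc, rmse


def classification_metrics(y_true: Sequence[float], y_pred: Sequence[float],
                           threshold: float = CLASSIFICATION_THRESHOLD
                           ) -> Tuple[float, float, float]:
    """Specificity, balanced accuracy, and AUC after thresholding true pKd.

    Predicted labels for specificity/BACC threshold y_pred at the same
    value; AUC uses raw y_pred as ranking scores (ties get half credit).
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    labels = yt >= threshold
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present after thresholding")
    pred_labels = yp >= threshold
    tn = np.sum(~labels & ~pred_labels)
    fp = np.sum(~labels & pred_labels)
    tp = np.sum(labels & pred_labels)
    fn = np.sum(labels & ~pred_labels)
    specificity = float(tn / (tn + fp))
    sensitivity = float(tp / (tp + fn))
    bacc = 0.5 * (specificity + sensitivity)
    auc = float(roc_auc_score(labels, yp))
    return specificity, bacc, auc


def evaluate_predictions(y_true: Sequence[float], y_pred: Sequence[float],
                         threshold: float = CLASSIFICATION_THRESHOLD
                         ) -> MetricsReport:
    pcc, scc, rmse = regression_metrics(y_true, y_pred)
    labels = np.asarray(y_true, dtype=float) >= threshold
    spec = bacc = auc = None
    if labels.any() and not labels.all():
        spec, bacc, auc = classification_metrics(y_true, y_pred, threshold)
    return MetricsReport(pcc, scc, rmse, spec, bacc, auc, n=len(y_true))


# --------------------------------------------------------------------------
# Similarity and leakage filtering
# --------------------------------------------------------------------------

def tanimoto(fp_a: FrozenSet[int], fp_b: FrozenSet[int]) -> float:
    """|A∩B| / |A∪B| over fingerprint bit sets; 0 when both are empty."""
    a, b = frozenset(fp_a), frozenset(fp_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fingerprint(mol_rec: MoleculeRecord) -> FrozenSet[int]:
    """Morgan (ECFP4-like) on-bit set for Tanimoto similarity."""
    fp = _MORGAN.GetFingerprint(mol_rec.mol())
    return frozenset(fp.GetOnBits())


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1.0
_ALIGNER.mismatch_score = 0.0
_ALIGNER.open_gap_score = 0.0
_ALIGNER.extend_gap_score = 0.0


def rna_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches under unit match score, zero
    mismatch/gap penalties, normalized by the longer length."""
    score = _ALIGNER.score(seq_a, seq_b)
    return float(score) / max(len(seq_a), len(seq_b))


@dataclass
class RemovalReport:
    removed_rnas: List[str] = field(default_factory=list)
    removed_mols: List[str] = field(default_factory=list)
    removed_pairs: int = 0


def independent_filter(train_ds: Dataset, test_ds: Dataset,
                       mol_sim_threshold: float = 0.8,
                       rna_id_threshold: float = 0.8
                       ) -> Tuple[Dataset, RemovalReport]:
    """Drop training entities too similar to any test entity.

    Molecules are compared by Morgan-fingerprint Tanimoto, RNAs by global
    sequence identity; thresholds are inclusive (similarity >= threshold
    removes).  Pairs touching a removed entity are dropped.
    """
    for t in (mol_sim_threshold, rna_id_threshold):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    test_fps = [morgan_fingerprint(m) for m in test_ds.molecules.values()]
    report = RemovalReport()
    bad_mols = set()
    for mid, mrec in train_ds.molecules.items():
        fp = morgan_fingerprint(mrec)
        if any(tanimoto(fp, tfp) >= mol_sim_threshold for tfp in test_fps):
            bad_mols.add(mid)
    bad_rnas = set()
    test_seqs = [r.sequence for r in test_ds.rnas.values()]
    for rid, rrec in train_ds.rnas.items():
        if any(rna_identity(rrec.sequence, ts) >= rna_id_threshold
               for ts in test_seqs):
            bad_rnas.add(rid)
    keep = [i for i, p in enumerate(train_ds.pairs)
            if p.rna_id not in bad_rnas and p.mol_id not in bad_mols]
    report.removed_rnas = sorted(bad_rnas)
    report.removed_mols = sorted(bad_mols)
    report.removed_pairs = len(train_ds.pairs) - len(keep)
    if not keep:
        raise ValueError("leakage filter removed every training pair")
    logger.info("independent filter removed %d RNAs, %d molecules, %d pairs",
                len(bad_rnas), len(bad_mols), report.removed_pairs)
    return train_ds.subset(keep), report


# --------------------------------------------------------------------------
# Cross-validation driver
# --------------------------------------------------------------------------

@dataclass
class CvResult:
    fold_reports: List[MetricsReport]
    aggregate_mean: Dict[str, float]
    aggregate_sd: Dict[str, float]
    predictions: Dict[int, np.ndarray]   # fold -> scores for its test pairs


def run_cv(dataset: Dataset, config: AffinityModelConfig,
           split_plan: SplitPlan, providers: Providers,
           seeds: Optional[Sequence[int]] = None) -> CvResult:
    """Train on k-1 folds, evaluate on the held-out fold, aggregate.

    With a seed list the whole CV repeats per seed and fold reports from
    all repeats enter the aggregate (mean and sd per metric).
    """
    seeds = list(seeds) if seeds is not None else [config.seed]
    fold_reports: List[MetricsReport] = []
    predictions: Dict[int, np.ndarray] = {}
    for seed in seeds:
        for fold in range(split_plan.k):
            test_idx = split_plan.fold_indices(fold)
            train_idx = np.flatnonzero(
                (split_plan.assignment >= 0) & (split_plan.assignment != fold))
            if len(test_idx) < 2:
                raise ValueError(f"fold {fold} has fewer than 2 test pairs")
            cfg = AffinityModelConfig(**{**config.__dict__, "seed": seed})
            result = train(dataset.subset(train_idx), cfg, providers)
            test_ds = dataset.subset(test_idx)
            store = FeatureStore(test_ds, providers, cfg)
            scores = predict_batch(test_ds, result.model, store)
            predictions[fold] = scores
            fold_reports.append(
                evaluate_predictions(test_ds.affinities, scores))
    keys = ["pcc", "scc", "rmse"]
    if all(r.auc is not None for r in fold_reports):
        keys += ["specificity", "bacc", "auc"]
    mean = {k: float(np.mean([getattr(r, k) for r in fold_reports]))
            for k in keys}
    sd = {k: float(np.std([getattr(r, k) for r in fold_reports]))
          for k in keys}
    return CvResult(fold_reports, mean, sd, predictions)
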
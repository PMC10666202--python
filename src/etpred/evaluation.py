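"""Chromosome-split cross-validation, PR metrics and dataset curation.

Cross-validation folds are unions of whole chromosomes (default 12 folds),
so a model is always tested on genomic regions disjoint from those it was
trained on — nearby pairs share features, and a random split would leak.
Evaluation uses the F1 score at the 0.5 calling threshold and the area
under the precision-recall curve, both suited to the heavy class imbalance
of enhancer–target candidates.

Dataset curation mirrors the benchmark construction: positives must have
an expressed target gene (TPM > 0); negatives are kept only when they
share a TSS or an enhancer with some positive; several assay-specific
datasets can be merged into a consensus set at a fixed negative:positive
ratio.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_recall_curve,
)

from . import classifier as clf
from .ct_features import ExpressionTable
from .genome_io import NEGATIVE, POSITIVE, CandidatePair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVFold:
    fold_id: int
    chromosomes: frozenset[str]
    train_indices: np.ndarray
    test_indices: np.ndarray


def chromosome_folds(
    chroms: Sequence[str] | Sequence[CandidatePair], k: int = 12
) -> list[CVFold]:
    """Partition pairs into k folds of whole chromosomes.

    Chromosomes are assigned greedily, largest pair count first, each to
    the currently lightest fold (ties: lower fold id; equal counts ordered
    by chromosome name), which balances fold sizes while keeping every
    chromosome wholly inside one fold.
    """
    if chroms and isinstance(chroms[0], CandidatePair):
        labels = np.array([p.tss.chrom for p in chroms])
    else:
        labels = np.asarray(chroms, dtype=object)
    counts = Counter(labels.tolist())
    if len(counts) < k:
        raise ValueError(
            f"only {len(counts)} chromosomes for k={k} folds; use a smaller k"
        )
    order = sorted(counts, key=lambda c: (-counts[c], c))
    loads = [0] * k
    assignment: dict[str, int] = {}
    for chrom in order:
        fold = int(np.argmin(loads))
        assignment[chrom] = fold
        loads[fold] += counts[chrom]
    folds = []
    all_idx = np.arange(labels.size)
    for fold_id in range(k):
        members = frozenset(c for c, f in assignment.items() if f == fold_id)
        test = all_idx[np.isin(labels, sorted(members))]
        train = all_idx[~np.isin(labels, sorted(members))]
        folds.append(CVFold(fold_id + 1, members, train, test))
    return folds


def folds_to_frame(folds: Sequence[CVFold]) -> pd.DataFrame:
    rows = [(c, f.fold_id) for f in folds for c in sorted(f.chromosomes)]
    return pd.DataFrame(rows, columns=["chrom", "fold_id"])


@dataclass
class PRMetrics:
    f1: float
    auprc: float
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"precision": self.precision, "recall": self.recall})


def pr_metrics(labels: np.ndarray, probabilities: np.ndarray) -> PRMetrics:
    """F1 at the 0.5 threshold plus AUPRC and the full PR curve."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics need both classes present in the labels")
    f1 = float(f1_score(y, (p > 0.5).astype(int), zero_division=0))
    auprc = float(average_precision_score(y, p))
    precision, recall, thresholds = precision_recall_curve(y, p)
    return PRMetrics(f1, auprc, precision, recall, thresholds)


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame
    oof_probs: np.ndarray
    f1: float
    auprc: float
    recall_at_half: float


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    folds: Sequence[CVFold],
    config: clf.ModelConfig,
) -> CVResult:
    """Train/test over chromosome folds; aggregate on pooled held-out scores."""
    y = np.asarray(labels, dtype=int)
    oof = np.zeros(y.shape[0])
    X = features.to_numpy(dtype=float)
    names = tuple(features.columns)
    rows = []
    for fold in folds:
        model = clf._fit(X[fold.train_indices], y[fold.train_indices], config, names)
        probs = model.estimator.predict_proba(
            pd.DataFrame(X[fold.test_indices], columns=list(names))
        )[:, 1]
        oof[fold.test_indices] = probs
        y_test = y[fold.test_indices]
        if len(np.unique(y_test)) == 2:
            m = pr_metrics(y_test, probs)
            rows.append((fold.fold_id, len(y_test), m.f1, m.auprc))
        else:
            rows.append((fold.fold_id, len(y_test), np.nan, np.nan))
    agg = pr_metrics(y, oof)
    pos = y == 1
    recall_at_half = float(np.mean(oof[pos] > 0.5)) if pos.any() else float("nan")
    return CVResult(
        pd.DataFrame(rows, columns=["fold_id", "n_test", "f1", "auprc"]),
        oof,
        agg.f1,
        agg.auprc,
        recall_at_half,
    )


# ---------------------------------------------------------------------------
# dataset curation


@dataclass
class LabeledDataset:
    pairs: list[CandidatePair]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"dataset {self.source!r} has duplicate pair ids")
        for p in self.pairs:
            if p.label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"pair {p.pair_id} is unlabeled")

    @property
    def n_positive(self) -> int:
        return sum(p.label == POSITIVE for p in self.pairs)


def filter_positives_by_expression(
    dataset: LabeledDataset, tpm_table: ExpressionTable
) -> LabeledDataset:
    """Drop positives whose target gene is unexpressed (TPM == 0).

    Negatives pass through untouched.  A positive whose gene is absent
    from the table is an input error, not a silent drop.
    """
    kept = []
    for p in dataset.pairs:
        if p.label == POSITIVE:
            tpm = tpm_table.get(p.tss.gene_id)  # raises on missing gene
            if tpm == 0:
                continue
        kept.append(p)
    logger.info(
        "expression filter: %d -> %d pairs (%s)",
        len(dataset.pairs), len(kept), dataset.source,
    )
    return LabeledDataset(kept, dataset.source)


def filter_matched_negatives(dataset: LabeledDataset) -> LabeledDataset:
    """Keep negatives sharing a TSS gene or an enhancer with some positive."""
    pos_genes = {p.tss.gene_id for p in dataset.pairs if p.label == POSITIVE}
    pos_enh = {p.enhancer.id for p in dataset.pairs if p.label == POSITIVE}
    if not pos_genes:
        raise ValueError("dataset has no positives to match negatives against")
    kept = [
        p
        for p in dataset.pairs
        if p.label == POSITIVE
        or p.tss.gene_id in pos_genes
        or p.enhancer.id in pos_enh
    ]
    logger.info(
        "matched-negative filter: %d -> %d pairs (%s)",
        len(dataset.pairs), len(kept), dataset.source,
    )
    return LabeledDataset(kept, dataset.source)


def build_consensus(
    datasets: Sequence[LabeledDataset], neg_ratio: float, seed: int
) -> LabeledDataset:
    """Merge datasets into one consensus set at a fixed negative:positive ratio.

    Pairs are keyed by (enhancer id, gene id); a pair positive in any
    source is positive in the consensus.  Negatives are subsampled without
    replacement (seeded) down to ``neg_ratio`` negatives per positive; if
    there are too few, all are kept with a warning.
    """
    if len(datasets) < 2:
        raise ValueError("consensus needs at least two datasets")
    merged: dict[tuple[str, str], CandidatePair] = {}
    for ds in datasets:
        for p in ds.pairs:
            key = (p.enhancer.id, p.tss.gene_id)
            prev = merged.get(key)
            if prev is None:
                merged[key] = p
            elif p.label == POSITIVE and prev.label != POSITIVE:
                merged[key] = p
    positives = [merged[k] for k in sorted(merged) if merged[k].label == POSITIVE]
    negatives = [merged[k] for k in sorted(merged) if merged[k].label == NEGATIVE]
    n_keep = int(neg_ratio * len(positives))
    if len(negatives) <= n_keep:
        logger.warning(
            "only %d negatives available for requested %d; keeping all",
            len(negatives), n_keep,
        )
        sampled = negatives
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(negatives), size=n_keep, replace=False))
        sampled = [negatives[i] for i in idx]
    return LabeledDataset(positives + sampled, source="consensus")
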
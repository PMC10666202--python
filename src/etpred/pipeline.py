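"""End-to-end feature computation: candidate pairs -> 28-feature table."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .activity_model import BinTrack, region_bin_probs
from .classifier import ModelConfig
from .ct_features import (
    FEATURE_NAMES,
    ExpressionTable,
    assemble_features,
    expression_feature,
    regulatory_distance,
)
from .evaluation import CVResult, chromosome_folds, cross_validate
from .generic_features import (
    CrossCTPanel,
    PanelMatrix,
    combined_tests_feature,
    genomic_distance,
)
from .genome_io import CandidatePair, extend_to_500bp, tss_region

logger = logging.getLogger(__name__)

META_COLUMNS = ("enhancer_id", "gene_id", "chrom", "label")


def compute_feature_table(
    pairs: Sequence[CandidatePair],
    track: BinTrack,
    expression: ExpressionTable,
    panels: Sequence[PanelMatrix] | dict[str, PanelMatrix] | None = None,
    crossct: CrossCTPanel | None = None,
) -> pd.DataFrame:
    """One row per candidate pair: metadata columns plus the 28 features.

    ``panels``/``crossct`` may be omitted (e.g. for purely cell-type-specific
    runs); the corresponding generic features are then 0.
    """
    if isinstance(panels, dict):
        panels = [panels[k] for k in sorted(panels)]
    rows = []
    meta = []
    for pair in pairs:
        enh_probs = region_bin_probs(track, extend_to_500bp(pair.enhancer))
        gene_probs = region_bin_probs(track, tss_region(pair.tss))
        rd_ep = regulatory_distance(track, pair, "EP")
        rd_pp = regulatory_distance(track, pair, "PP")
        tpm = expression_feature(pair.tss.gene_id, expression)
        cor = (
            crossct.pair_correlation(pair.enhancer.id, pair.tss.gene_id)
            if crossct is not None
            else 0.0
        )
        combined = (
            combined_tests_feature(panels, pair.enhancer.id, pair.tss.gene_id)
            if panels
            else 0.0
        )
        rows.append(
            assemble_features(
                pair,
                enh_probs,
                gene_probs,
                rd_ep,
                rd_pp,
                tpm,
                genomic_distance(pair),
                cor,
                combined,
            )
        )
        meta.append(
            (pair.pair_id, pair.enhancer.id, pair.tss.gene_id, pair.tss.chrom, pair.label)
        )
    meta_df = pd.DataFrame(
        meta, columns=["pair_id", *META_COLUMNS]
    ).set_index("pair_id")
    if not rows:
        feats = pd.DataFrame(columns=list(FEATURE_NAMES))
        feats.index.name = "pair_id"
        return pd.concat([meta_df, feats], axis=1)
    feats = pd.DataFrame(rows, index=meta_df.index)
    logger.info("computed %d feature rows x %d features", *feats.shape)
    return pd.concat([meta_df, feats], axis=1)


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The bare 28-column matrix from a full feature table."""
    return table[list(FEATURE_NAMES)]


def labels_from_table(table: pd.DataFrame) -> np.ndarray:
    labs = table["label"].to_numpy()
    if not set(np.unique(labs)) <= {"positive", "negative"}:
        raise ValueError("feature table contains unlabeled pairs")
    return (labs == "positive").astype(int)


def evaluate_table(
    table: pd.DataFrame, config: ModelConfig, k: int = 12
) -> tuple[CVResult, list]:
    """Chromosome-split cross-validation of a labeled feature table."""
    folds = chromosome_folds(table["chrom"].tolist(), k=k)
    result = cross_validate(
        feature_matrix(table), labels_from_table(table), folds, config
    )
    return result, folds
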
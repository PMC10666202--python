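"""Cell-type-specific features and assembly of the 28-feature vector.

The feature schema is fixed: 10 enhancer-probability values (5 on the
element, 5 on the TSS), 10 promoter-probability values, the four
regulatory-distance values, the target gene's expression (TPM), the
genomic distance, and the two cross-biosample statistics.  Feature names
and order are a contract — the classifier, model manifests and importance
reports all key on them.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity_model import BIN_SIZE, BinTrack, RegionProbs, region_bin_probs
from .genome_io import CandidatePair, MAX_PAIR_DISTANCE, extend_to_500bp, tss_region

logger = logging.getLogger(__name__)

#: The 28 feature names, in fixed schema order.
FEATURE_NAMES: tuple[str, ...] = (
    *(f"EP_prob_enh.{i}" for i in range(1, 6)),
    *(f"EP_prob_gene.{i}" for i in range(1, 6)),
    "reg_dist_enh",
    "norm_reg_dist_enh",
    *(f"PP_prob_enh.{i}" for i in range(1, 6)),
    *(f"PP_prob_gene.{i}" for i in range(1, 6)),
    "reg_dist_prom",
    "norm_reg_dist_prom",
    "RNA_seq",
    "Distance",
    "cor_CRUP",
    "combined_tests",
)

#: The generic (cell-type-agnostic) features among the 28.
GENERIC_FEATURE_NAMES: tuple[str, ...] = ("combined_tests", "cor_CRUP", "Distance")


class AssemblyError(ValueError):
    """Raised when the feature vector cannot be assembled."""


class ExpressionTable:
    """gene_id -> TPM lookup; missing genes raise instead of silently 0."""

    def __init__(self, tpm: Mapping[str, float] | pd.Series):
        series = pd.Series(tpm, dtype=float)
        if (series < 0).any():
            raise ValueError("TPM values must be nonnegative")
        self._tpm = series

    def __len__(self) -> int:
        return len(self._tpm)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._tpm.index

    def get(self, gene_id: str) -> float:
        if gene_id not in self._tpm.index:
            raise LookupError(f"gene {gene_id!r} missing from expression table")
        return float(self._tpm[gene_id])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "TPM"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns gene_id, TPM")
        return cls(pd.Series(df["TPM"].to_numpy(), index=df["gene_id"].astype(str)))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene_id": self._tpm.index, "TPM": self._tpm.to_numpy()})
        df.to_csv(path, sep="\t", index=False)


def expression_feature(gene_id: str, table: ExpressionTable) -> float:
    """TPM of the target gene in the cell type of interest."""
    return table.get(gene_id)


def regulatory_distance(
    track: BinTrack, pair: CandidatePair, channel: str
) -> tuple[int, float]:
    """Regulatory-distance pair: active-bin count and fraction in the window.

    The window is the open interval between the two extended 500 bp
    regions, snapped inward to the 100 bp grid so that no bin overlapping
    either region is counted.  A bin is active when the requested channel
    (EP or PP) probability strictly exceeds 0.5.  An empty window yields
    ``(0, 0.0)``.
    """
    if channel not in ("EP", "PP"):
        raise ValueError(f"channel must be 'EP' or 'PP', got {channel!r}")
    enh500 = extend_to_500bp(pair.enhancer)
    prom500 = tss_region(pair.tss)
    left, right = sorted((enh500, prom500), key=lambda r: (r.start, r.end))
    w_start = -(-left.end // BIN_SIZE) * BIN_SIZE  # ceil to grid
    w_end = (right.start // BIN_SIZE) * BIN_SIZE  # floor to grid
    if w_end <= w_start:
        return 0, 0.0
    pa, pe = track.window_probs(pair.tss.chrom, w_start, w_end)
    vals = pa * pe if channel == "EP" else pa * (1.0 - pe)
    count = int(np.count_nonzero(vals > 0.5))
    return count, count / vals.size


def assemble_features(
    pair: CandidatePair,
    enh_probs: RegionProbs,
    gene_probs: RegionProbs,
    rd_ep: tuple[int, float],
    rd_pp: tuple[int, float],
    tpm: float,
    distance: int,
    cor_crup: float,
    combined_tests: float,
) -> pd.Series:
    """Assemble the named 28-feature vector for one candidate pair.

    Assembly is by name, so the order in which components were computed is
    irrelevant; the output index always equals :data:`FEATURE_NAMES`.
    """
    components = {
        "pair": pair,
        "enh_probs": enh_probs,
        "gene_probs": gene_probs,
        "rd_ep": rd_ep,
        "rd_pp": rd_pp,
        "tpm": tpm,
        "distance": distance,
        "cor_crup": cor_crup,
        "combined_tests": combined_tests,
    }
    missing = [k for k, v in components.items() if v is None]
    if missing:
        raise AssemblyError(f"missing feature components: {missing}")

    values: dict[str, float] = {}
    for i in range(5):
        values[f"EP_prob_enh.{i + 1}"] = float(enh_probs.ep[i])
        values[f"EP_prob_gene.{i + 1}"] = float(gene_probs.ep[i])
        values[f"PP_prob_enh.{i + 1}"] = float(enh_probs.pp[i])
        values[f"PP_prob_gene.{i + 1}"] = float(gene_probs.pp[i])
    values["reg_dist_enh"], values["norm_reg_dist_enh"] = rd_ep
    values["reg_dist_prom"], values["norm_reg_dist_prom"] = rd_pp
    values["RNA_seq"] = float(tpm)
    values["Distance"] = float(distance)
    values["cor_CRUP"] = float(cor_crup)
    values["combined_tests"] = float(combined_tests)

    _validate(values)
    return pd.Series([values[name] for name in FEATURE_NAMES], index=FEATURE_NAMES)


def _validate(values: dict[str, float]) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise AssemblyError(f"feature {name} is not finite: {v}")
    for name in FEATURE_NAMES:
        if name.startswith(("EP_prob", "PP_prob")) and not 0 <= values[name] <= 1:
            raise AssemblyError(f"{name}={values[name]} outside [0, 1]")
    for name in ("reg_dist_enh", "reg_dist_prom"):
        if values[name] < 0 or values[name] != int(values[name]):
            raise AssemblyError(f"{name} must be a nonnegative integer")
    for name in ("norm_reg_dist_enh", "norm_reg_dist_prom"):
        if not 0 <= values[name] <= 1:
            raise AssemblyError(f"{name}={values[name]} outside [0, 1]")
    if not 0 <= values["Distance"] <= MAX_PAIR_DISTANCE:
        raise AssemblyError(f"Distance={values['Distance']} outside window")
    if values["RNA_seq"] < 0:
        raise AssemblyError("RNA_seq must be nonnegative")
    if values["combined_tests"] < 0:
        raise AssemblyError("combined_tests must be nonnegative")
    if not -1 <= values["cor_CRUP"] <= 1:
        raise AssemblyError(f"cor_CRUP={values['cor_CRUP']} outside [-1, 1]")
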
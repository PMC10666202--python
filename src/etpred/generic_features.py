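"""Cross-biosample (generic) evidence for candidate pairs.

Three generic features feed the classifier:

* ``combined_tests`` — four activity-split Wilcoxon rank-sum tests, one per
  signal panel (CAGE enhancer expression, DNase accessibility, DNase vs
  microarray expression, activity-probability vs expression), combined into
  one p-value with Fisher's method and reported as its negative natural
  logarithm;
* ``cor_CRUP`` — Pearson correlation, across a panel of cell types, of the
  enhancer's summed 5-bin enhancer probability with the target's summed
  5-bin promoter probability;
* ``Distance`` — absolute genomic distance between enhancer midpoint and TSS.

Each rank-sum test splits the biosamples by an activity rule on the
enhancer's signal (expressed / top-quartile accessible / mean probability
above 0.5) and asks, one-sided, whether the target's signal is greater in
the enhancer-active biosamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CandidatePair, GenomicRegion

logger = logging.getLogger(__name__)

TPM_POSITIVE = "tpm_positive"
TOP_QUANTILE = "top_quantile_0.25"
MEAN_EP = "mean_ep_gt_0.5"
ACTIVITY_RULES = (TPM_POSITIVE, TOP_QUANTILE, MEAN_EP)

PANEL_KINDS = ("CAGE", "DHS", "DHS_EXPR", "CRUP_EXPR")
DEFAULT_PANEL_RULES = {
    "CAGE": TPM_POSITIVE,
    "DHS": TOP_QUANTILE,
    "DHS_EXPR": TOP_QUANTILE,
    "CRUP_EXPR": MEAN_EP,
}

_P_FLOOR = 1e-300
#: largest group size handled by exact rank-sum enumeration
_EXACT_MAX = 8


def activity_split(enh_row: np.ndarray, rule: str) -> np.ndarray:
    """Boolean mask of enhancer-active biosamples under a named rule.

    ``top_quantile_0.25`` selects exactly ``ceil(0.25 * n)`` biosamples,
    ranking by signal and breaking ties by biosample index so membership is
    deterministic.
    """
    values = np.asarray(enh_row, dtype=float)
    if values.size == 0:
        raise ValueError("activity_split needs a nonempty signal vector")
    if rule == TPM_POSITIVE:
        return values > 0
    if rule == MEAN_EP:
        return values > 0.5
    if rule == TOP_QUANTILE:
        k = math.ceil(0.25 * values.size)
        order = np.lexsort((np.arange(values.size), -values))
        mask = np.zeros(values.size, dtype=bool)
        mask[order[:k]] = True
        return mask
    raise ValueError(f"unknown activity rule {rule!r}")


def rank_sum_test(target_row: np.ndarray, active_mask: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value: target greater where active.

    Small problems (both groups of size <= 8) are solved by exhaustive
    enumeration of all group assignments of the pooled midranks; larger
    ones use the normal approximation with tie correction and continuity
    correction.  If either group is empty the test is undefined and the
    p-value is 1.
    """
    target = np.asarray(target_row, dtype=float)
    mask = np.asarray(active_mask, dtype=bool)
    if target.shape != mask.shape:
        raise ValueError("target vector and activity mask lengths differ")
    x = target[mask]
    y = target[~mask]
    if x.size == 0 or y.size == 0:
        return 1.0
    if max(x.size, y.size) <= _EXACT_MAX:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        observed = ranks[: x.size].sum()
        n = pooled.size
        hits = total = 0
        for idx in combinations(range(n), x.size):
            total += 1
            if ranks[list(idx)].sum() >= observed - 1e-9:
                hits += 1
        return hits / total
    if np.ptp(target) == 0:
        return 1.0  # all values identical: no evidence in either direction
    res = stats.mannwhitneyu(
        x, y, alternative="greater", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def aggregate_overlaps(
    element: GenomicRegion, peaks: Sequence[tuple[GenomicRegion, float]]
) -> float:
    """Sum of peak values overlapping the element by >= 1 bp (half-open)."""
    return float(
        sum(value for region, value in peaks if element.overlaps(region))
    )


class FisherResult(NamedTuple):
    combined_p: float
    neg_log_p: float
    statistic: float
    df: int


def fisher_combine(pvals: Sequence[float]) -> FisherResult:
    """Fisher's method over the available panel p-values.

    The statistic ``-2 * sum(ln p_i)`` is referred to a chi-square
    distribution with ``2k`` degrees of freedom, where ``k`` is the number
    of p-values actually supplied (panels without coverage are omitted
    upstream, shrinking k).  Underflowing p-values are clamped at 1e-300 so
    the negative logarithm stays finite.
    """
    ps = np.asarray(pvals, dtype=float)
    if ps.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in [0, 1]")
    ps = np.clip(ps, _P_FLOOR, 1.0)
    statistic = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    combined = float(stats.chi2.sf(statistic, df))
    neg_log = float(-np.log(max(combined, _P_FLOOR)))
    return FisherResult(combined, neg_log, statistic, df)


def crup_correlation(enh_ep_sum: np.ndarray, gene_pp_sum: np.ndarray) -> float:
    """Pearson correlation of per-biosample EP sums vs PP sums.

    If either vector has zero variance the correlation is undefined and is
    reported as 0 (no evidence of co-variation).
    """
    e = np.asarray(enh_ep_sum, dtype=float)
    g = np.asarray(gene_pp_sum, dtype=float)
    if e.shape != g.shape:
        raise ValueError(f"vector length mismatch: {e.shape} vs {g.shape}")
    if e.size < 2:
        raise ValueError("need at least two biosamples for a correlation")
    if np.std(e) == 0 or np.std(g) == 0:
        return 0.0
    return float(np.corrcoef(e, g)[0, 1])


def genomic_distance(pair: CandidatePair) -> int:
    """Absolute distance between the enhancer midpoint and the TSS, in bp."""
    return abs(pair.enhancer.midpoint() - pair.tss.pos)


@dataclass
class PanelMatrix:
    """One cross-biosample signal panel (elements x biosamples).

    ``enh_signal`` rows are enhancer elements, ``target_signal`` rows are
    targets (genes); both share the biosample axis.  An element missing
    from a matrix counts as *not measured* in this panel — distinct from a
    present all-zero row, which is a valid measurement.
    """

    kind: str
    enh_signal: pd.DataFrame
    target_signal: pd.DataFrame
    activity_rule: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PANEL_KINDS:
            raise ValueError(f"unknown panel kind {self.kind!r}")
        if not self.activity_rule:
            self.activity_rule = DEFAULT_PANEL_RULES[self.kind]
        if self.activity_rule not in ACTIVITY_RULES:
            raise ValueError(f"unknown activity rule {self.activity_rule!r}")
        if list(self.enh_signal.columns) != list(self.target_signal.columns):
            raise ValueError(f"{self.kind}: panels must share the biosample axis")
        if self.activity_rule == TPM_POSITIVE and (self.enh_signal < 0).any().any():
            raise ValueError(f"{self.kind}: negative signal under a TPM rule")

    @property
    def n_biosamples(self) -> int:
        return self.enh_signal.shape[1]

    def pair_pvalue(self, enh_id: str, target_id: str) -> float | None:
        """Activity-split rank-sum p-value, or None when not measured."""
        if enh_id not in self.enh_signal.index:
            return None
        if target_id not in self.target_signal.index:
            return None
        enh_row = self.enh_signal.loc[enh_id].to_numpy(dtype=float)
        target_row = self.target_signal.loc[target_id].to_numpy(dtype=float)
        mask = activity_split(enh_row, self.activity_rule)
        return rank_sum_test(target_row, mask)


def combined_tests_feature(
    panels: Sequence[PanelMatrix], enh_id: str, target_id: str
) -> float:
    """negative log Fisher-combined p over the panels covering the pair.

    Panels where the enhancer or target is not measured drop out of the
    combination (the chi-square degrees of freedom shrink).  A pair covered
    by no panel carries no cross-biosample evidence and scores 0.
    """
    pvals = []
    for panel in panels:
        p = panel.pair_pvalue(enh_id, target_id)
        if p is not None:
            pvals.append(p)
    if not pvals:
        logger.warning(
            "pair (%s, %s) not measured in any panel; combined_tests = 0",
            enh_id, target_id,
        )
        return 0.0
    return fisher_combine(pvals).neg_log_p


@dataclass
class CrossCTPanel:
    """Summed 5-bin EP/PP probabilities across a panel of cell types."""

    enh_ep_sum: pd.DataFrame  # enhancers x cell types
    gene_pp_sum: pd.DataFrame  # genes x cell types

    def __post_init__(self) -> None:
        if list(self.enh_ep_sum.columns) != list(self.gene_pp_sum.columns):
            raise ValueError("cross-CT matrices must share the cell-type axis")

    def pair_correlation(self, enh_id: str, gene_id: str) -> float:
        if enh_id not in self.enh_ep_sum.index or gene_id not in self.gene_pp_sum.index:
            logger.warning(
                "pair (%s, %s) missing from cross-CT panel; cor_CRUP = 0",
                enh_id, gene_id,
            )
            return 0.0
        return crup_correlation(
            self.enh_ep_sum.loc[enh_id].to_numpy(dtype=float),
            self.gene_pp_sum.loc[gene_id].to_numpy(dtype=float),
        )
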
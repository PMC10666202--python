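"""Two-stage activity-probability algebra on 100 bp bin tracks.

A genome is tiled into 100 bp bins.  For the cell type of interest, each
bin carries two probabilities produced by a two-stage classifier over
histone-modification signals (H3K27ac, H3K4me1, H3K4me3):

* ``p_active`` — probability the bin is an active regulatory region
  (stage 1: active vs inactive);
* ``p_enh_given_active`` — probability the bin is an enhancer given it is
  active (stage 2: enhancer vs promoter among active bins).

The two channels combine into the enhancer probability
``EP = p_active * p_enh_given_active`` and, using the complement of the
second stage, the promoter probability
``PP = p_active * (1 - p_enh_given_active)``, so EP + PP = p_active per
bin.  Candidate elements and TSSs are profiled on 500 bp windows, yielding
five EP and five PP values per region.

:func:`train_two_stage` fits a self-contained random-forest two-stage model
from per-bin signal matrices so the whole pipeline can run on simulated
histone-signal data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .genome_io import GenomicRegion

logger = logging.getLogger(__name__)

BIN_SIZE = 100

INACTIVE = "inactive"
ACTIVE_ENHANCER = "active_enhancer"
ACTIVE_PROMOTER = "active_promoter"


def ep_probability(p_active: float, p_enh_given_active: float) -> float:
    """Enhancer probability of a bin: P(active) * P(enhancer | active)."""
    return p_active * p_enh_given_active


def pp_probability(p_active: float, p_enh_given_active: float) -> float:
    """Promoter probability of a bin: P(active) * (1 - P(enhancer | active))."""
    return p_active * (1.0 - p_enh_given_active)


@dataclass(frozen=True)
class RegionProbs:
    """Five EP and five PP values for one 500 bp region, left to right."""

    region_id: str
    ep: np.ndarray
    pp: np.ndarray

    def __post_init__(self) -> None:
        ep = np.asarray(self.ep, dtype=float)
        pp = np.asarray(self.pp, dtype=float)
        object.__setattr__(self, "ep", ep)
        object.__setattr__(self, "pp", pp)
        for name, arr in (("ep", ep), ("pp", pp)):
            if arr.shape != (5,):
                raise ValueError(f"{name} must hold exactly 5 values, got {arr.shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")


def mean_ep_active(probs: RegionProbs) -> bool:
    """Is the region an active enhancer, i.e. mean EP strictly above 0.5?"""
    return float(np.mean(probs.ep)) > 0.5


@dataclass
class _ChromTrack:
    start_bin: int  # bp of the first stored bin (multiple of BIN_SIZE)
    p_active: np.ndarray
    p_enh: np.ndarray
    covered: np.ndarray  # bool; False where the source track had no bin


class BinTrack:
    """Dense per-chromosome store of the two-channel 100 bp probability track.

    Bins absent from the source data are treated as
    ``(p_active=0, p_enh_given_active=0)`` — absent signal is read as
    inactive — and flagged so lookups can warn.
    """

    def __init__(self, chrom_data: dict[str, _ChromTrack]):
        self._chroms = chrom_data

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    @classmethod
    def from_arrays(
        cls, chrom_map: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> "BinTrack":
        """Build from ``{chrom: (bin_starts, p_active, p_enh_given_active)}``."""
        data: dict[str, _ChromTrack] = {}
        for chrom, (starts, pa, pe) in chrom_map.items():
            starts = np.asarray(starts, dtype=np.int64)
            pa = np.asarray(pa, dtype=float)
            pe = np.asarray(pe, dtype=float)
            if starts.size == 0:
                continue
            if np.any(starts % BIN_SIZE != 0):
                raise ValueError(f"{chrom}: bin starts must align to the 100 bp grid")
            if np.unique(starts).size != starts.size:
                raise ValueError(f"{chrom}: duplicate bins")
            for name, arr in (("p_active", pa), ("p_enh_given_active", pe)):
                if np.any(arr < 0) or np.any(arr > 1):
                    raise ValueError(f"{chrom}: {name} outside [0, 1]")
            lo, hi = int(starts.min()), int(starts.max())
            n = (hi - lo) // BIN_SIZE + 1
            dense_pa = np.zeros(n)
            dense_pe = np.zeros(n)
            covered = np.zeros(n, dtype=bool)
            idx = (starts - lo) // BIN_SIZE
            dense_pa[idx] = pa
            dense_pe[idx] = pe
            covered[idx] = True
            data[chrom] = _ChromTrack(lo, dense_pa, dense_pe, covered)
        return cls(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinTrack":
        """Build from a bedGraph-like table (chrom, start, end, two channels)."""
        required = {"chrom", "start", "end", "p_active", "p_enh_given_active"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")
        if np.any(df["end"].to_numpy() - df["start"].to_numpy() != BIN_SIZE):
            raise ValueError("every track interval must span exactly 100 bp")
        chrom_map = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            chrom_map[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["p_active"].to_numpy(),
                sub["p_enh_given_active"].to_numpy(),
            )
        return cls.from_arrays(chrom_map)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            ct = self._chroms[chrom]
            starts = ct.start_bin + BIN_SIZE * np.flatnonzero(ct.covered)
            idx = (starts - ct.start_bin) // BIN_SIZE
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + BIN_SIZE,
                        "p_active": ct.p_active[idx],
                        "p_enh_given_active": ct.p_enh[idx],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["chrom", "start", "end", "p_active", "p_enh_given_active"]
            )
        return pd.concat(rows, ignore_index=True)

    def probs_at(
        self, chrom: str, bin_starts: np.ndarray, warn: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """(p_active, p_enh_given_active) for the requested grid bins."""
        bin_starts = np.asarray(bin_starts, dtype=np.int64)
        if np.any(bin_starts % BIN_SIZE != 0):
            raise ValueError("requested positions must align to the 100 bp grid")
        pa = np.zeros(bin_starts.size)
        pe = np.zeros(bin_starts.size)
        ct = self._chroms.get(chrom)
        if ct is None:
            if warn and bin_starts.size:
                logger.warning("no track data for %s; treating bins as inactive", chrom)
            return pa, pe
        idx = (bin_starts - ct.start_bin) // BIN_SIZE
        inside = (idx >= 0) & (idx < ct.p_active.size)
        hit = inside.copy()
        hit[inside] = ct.covered[idx[inside]]
        if warn and not np.all(hit):
            logger.warning(
                "%d/%d bins missing from track on %s; treated as inactive",
                int((~hit).sum()), bin_starts.size, chrom,
            )
        pa[hit] = ct.p_active[idx[hit]]
        pe[hit] = ct.p_enh[idx[hit]]
        return pa, pe

    def window_probs(
        self, chrom: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Channel probabilities for all full grid bins in ``[start, end)``."""
        if start % BIN_SIZE or end % BIN_SIZE:
            raise ValueError("window bounds must align to the 100 bp grid")
        if end <= start:
            return np.zeros(0), np.zeros(0)
        bins = np.arange(start, end, BIN_SIZE, dtype=np.int64)
        return self.probs_at(chrom, bins, warn=False)


def region_bin_probs(track: BinTrack, region500: GenomicRegion) -> RegionProbs:
    """Profile a 500 bp region into its five EP and five PP values.

    Grid-aligned regions cover exactly five bins.  A misaligned region
    overlaps six bins; the five with the largest overlap are kept, and the
    50/50 tie between the two flanking half-bins drops the rightmost.
    """
    if region500.length != 500:
        raise ValueError(
            f"region {region500.id} must be exactly 500 bp, got {region500.length}"
        )
    start = region500.start
    if start % BIN_SIZE == 0:
        bins = start + BIN_SIZE * np.arange(5, dtype=np.int64)
    else:
        b0 = (start // BIN_SIZE) * BIN_SIZE
        six = b0 + BIN_SIZE * np.arange(6, dtype=np.int64)
        first_overlap = b0 + BIN_SIZE - start
        last_overlap = region500.end - (b0 + 5 * BIN_SIZE)
        bins = six[1:] if first_overlap < last_overlap else six[:5]
    pa, pe = track.probs_at(region500.chrom, bins)
    return RegionProbs(region500.id, ep=pa * pe, pp=pa * (1.0 - pe))


class TwoStageActivityModel:
    """Random-forest two-stage model mapping per-bin signals to probabilities.

    Stage 1 separates active bins (enhancers and promoters) from inactive
    ones; stage 2, fitted only on active bins, separates enhancers from
    promoters.  This is a self-contained learner over per-bin feature
    matrices — the package does not reprocess ChIP-seq reads.
    """

    def __init__(self, seed: int = 0, n_estimators: int = 100):
        self.seed = seed
        self.n_estimators = n_estimators
        self._stage1: RandomForestClassifier | None = None
        self._stage2: RandomForestClassifier | None = None
        self._stage2_const: float | None = None

    def fit(self, bin_features: np.ndarray, labels: np.ndarray) -> "TwoStageActivityModel":
        X = np.asarray(bin_features, dtype=float)
        labels = np.asarray(labels)
        classes = set(np.unique(labels))
        bad = classes - {INACTIVE, ACTIVE_ENHANCER, ACTIVE_PROMOTER}
        if bad:
            raise ValueError(f"unknown bin labels {sorted(bad)}")
        if len(classes) < 2:
            raise ValueError("need at least two bin classes to train")
        active = labels != INACTIVE
        if active.all() or not active.any():
            raise ValueError("stage 1 needs both active and inactive bins")
        self._stage1 = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        ).fit(X, active)
        enh = labels[active] == ACTIVE_ENHANCER
        if enh.all() or not enh.any():
            self._stage2 = None
            self._stage2_const = 1.0 if enh.all() else 0.0
            logger.warning(
                "single active class; stage 2 collapses to constant %.1f",
                self._stage2_const,
            )
        else:
            self._stage2 = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.seed + 1, n_jobs=1
            ).fit(X[active], enh)
        return self

    def predict_bins(self, bin_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(p_active, p_enh_given_active) per input bin."""
        if self._stage1 is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(bin_features, dtype=float)
        pa = self._stage1.predict_proba(X)[:, list(self._stage1.classes_).index(True)]
        if self._stage2 is None:
            pe = np.full(X.shape[0], self._stage2_const)
        else:
            pe = self._stage2.predict_proba(X)[
                :, list(self._stage2.classes_).index(True)
            ]
        return pa, pe

    def predict_track(
        self, bin_features: np.ndarray, chrom: str, bin_starts: np.ndarray
    ) -> BinTrack:
        pa, pe = self.predict_bins(bin_features)
        return BinTrack.from_arrays({chrom: (np.asarray(bin_starts), pa, pe)})


def train_two_stage(
    bin_features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> TwoStageActivityModel:
    """Fit the two-stage activity model; see :class:`TwoStageActivityModel`."""
    return TwoStageActivityModel(seed=seed).fit(bin_features, labels)


def read_track(path: str | Path) -> BinTrack:
    """Read a combined 5-column track TSV (chrom, start, end, two channels)."""
    return BinTrack.from_frame(pd.read_csv(path, sep="\t"))


def write_track(track: BinTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)
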
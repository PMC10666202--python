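"""Genomic coordinate model, interval I/O and candidate-pair enumeration.

All coordinates are 0-based half-open ``[start, end)`` — the BED convention —
throughout the package.  GTF input (1-based, closed intervals) is converted
at the parser boundary so no other module ever sees 1-based coordinates.

The central objects are putative enhancer elements (:class:`GenomicRegion`),
gene transcription start sites (:class:`TSSRecord`) and candidate
enhancer–target pairs (:class:`CandidatePair`).  Candidate pairs are
restricted to the same chromosome and to a midpoint-to-TSS distance of at
most 500 kb, the commonly accepted upper bound for enhancer–promoter
interactions (roughly the median size of a topologically associating
domain).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum candidate enhancer-TSS distance in bp (inclusive bound).
MAX_PAIR_DISTANCE = 500_000

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
_LABELS = (POSITIVE, NEGATIVE, UNLABELED)


class ParseError(ValueError):
    """Raised when a genomic input file cannot be parsed."""


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A half-open genomic interval with an element identifier."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"region start must be < end, got [{self.start}, {self.end})"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        """Midpoint in bp; even-length regions round down (floor rule)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class TSSRecord:
    """A transcription start site, one per gene after 5'-most collapsing."""

    chrom: str
    pos: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True, slots=True)
class CandidatePair:
    """A candidate enhancer–target pair within the 500 kb search window."""

    enhancer: GenomicRegion
    tss: TSSRecord
    distance_bp: int
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.enhancer.chrom != self.tss.chrom:
            raise ValueError(
                "candidate pair must be on one chromosome: "
                f"{self.enhancer.chrom} vs {self.tss.chrom}"
            )
        expected = abs(self.enhancer.midpoint() - self.tss.pos)
        if self.distance_bp != expected:
            raise ValueError(
                f"distance_bp {self.distance_bp} != |midpoint - tss| {expected}"
            )
        if self.distance_bp > MAX_PAIR_DISTANCE:
            raise ValueError(
                f"pair distance {self.distance_bp} exceeds {MAX_PAIR_DISTANCE}"
            )
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def pair_id(self) -> str:
        return f"{self.enhancer.id}--{self.tss.gene_id}"

    def with_label(self, label: str) -> "CandidatePair":
        return replace(self, label=label)


def midpoint(region: GenomicRegion) -> int:
    """Midpoint of a region, floor((start + end) / 2)."""
    return region.midpoint()


def extend_to_500bp(region: GenomicRegion, length: int = 500) -> GenomicRegion:
    """Extend a region symmetrically around its midpoint to ``length`` bp.

    Elements have variable native size (catalogued enhancer-like elements
    run ~150-350 bp); features are computed on fixed 500 bp windows centred
    on the element midpoint.  A window that would start before the
    chromosome origin is clamped to ``[0, length)`` with a warning.
    """
    mid = region.midpoint()
    start = mid - length // 2
    if start < 0:
        logger.warning(
            "extended region for %s would start at %d; clamped to [0, %d)",
            region.id, start, length,
        )
        start = 0
    return GenomicRegion(region.chrom, start, start + length, region.id)


def tss_region(tss: TSSRecord, length: int = 500) -> GenomicRegion:
    """The 500 bp window centred on a TSS, as a region carrying the gene id."""
    point = GenomicRegion(tss.chrom, tss.pos, tss.pos + 1, tss.gene_id)
    return extend_to_500bp(point, length=length)


# ---------------------------------------------------------------------------
# readers / writers


def read_regions(path: str | Path) -> list[GenomicRegion]:
    """Read elements from a BED file (3+ columns, 4th column = id if present)."""
    regions: list[GenomicRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else ""
            try:
                region = GenomicRegion(chrom, start, end, name)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if region.id in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate element id {region.id!r}"
                )
            seen.add(region.id)
            regions.append(region)
    return regions


def write_regions(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write elements as 4-column BED."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


_GENE_ID_RE = re.compile(r'gene_id\s+"?([^";]+)"?')


def _looks_like_gtf(path: str | Path) -> bool:
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            return len(fields) >= 9 and "gene_id" in fields[8]
    return False


def read_tss(path: str | Path, collapse: bool = True) -> list[TSSRecord]:
    """Read TSS records from a GTF (GENCODE dialect) or a TSV file.

    GTF ``gene`` records (falling back to ``transcript`` records when no
    gene rows exist) define one TSS per feature: the interval start for +
    strand, the interval end for - strand, converted to 0-based
    coordinates.  With ``collapse=True`` (default) each gene contributes a
    single record, its 5'-most TSS; ``collapse=False`` keeps every distinct
    TSS per gene.  The TSV dialect needs columns gene_id, chrom, pos,
    strand with 0-based positions.
    """
    if _looks_like_gtf(path):
        records = _read_tss_gtf(path)
    else:
        records = _read_tss_tsv(path)
    if not collapse:
        # unique (gene, pos) records, stable input order
        uniq = {(t.gene_id, t.pos): t for t in records}
        return list(uniq.values())
    by_gene: dict[str, TSSRecord] = {}
    for t in records:
        prev = by_gene.get(t.gene_id)
        if prev is None:
            by_gene[t.gene_id] = t
        elif t.strand == "+" and t.pos < prev.pos:
            by_gene[t.gene_id] = t
        elif t.strand == "-" and t.pos > prev.pos:
            by_gene[t.gene_id] = t
    return list(by_gene.values())


def _read_tss_gtf(path: str | Path) -> list[TSSRecord]:
    genes: list[TSSRecord] = []
    transcripts: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF columns")
            feature = fields[2]
            if feature not in ("gene", "transcript"):
                continue
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            # GTF is 1-based closed; TSS = start for +, end for -
            pos = start1 - 1 if strand == "+" else end1 - 1
            rec = TSSRecord(fields[0], pos, gene_id, strand)
            (genes if feature == "gene" else transcripts).append(rec)
    return genes if genes else transcripts


def _read_tss_tsv(path: str | Path) -> list[TSSRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing TSS columns {sorted(missing)}")
    return [
        TSSRecord(str(r.chrom), int(r.pos), str(r.gene_id), str(r.strand))
        for r in df.itertuples()
    ]


def write_tss(records: Iterable[TSSRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.gene_id, t.chrom, t.pos, t.strand) for t in records],
        columns=["gene_id", "chrom", "pos", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_candidates(
    tss_list: Sequence[TSSRecord],
    enhancer_list: Sequence[GenomicRegion],
    max_dist: int = MAX_PAIR_DISTANCE,
) -> list[CandidatePair]:
    """All same-chromosome (TSS, enhancer) pairs within ``max_dist`` bp.

    The distance is measured from the original element midpoint to the TSS
    and the bound is inclusive.  Output order is deterministic: sorted by
    chromosome, TSS position, then enhancer midpoint.
    """
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for enh in enhancer_list:
        by_chrom.setdefault(enh.chrom, []).append(enh)
    for chrom_enh in by_chrom.values():
        chrom_enh.sort(key=lambda e: (e.midpoint(), e.id))

    pairs: list[CandidatePair] = []
    for tss in sorted(tss_list, key=lambda t: (t.chrom, t.pos, t.gene_id)):
        for enh in by_chrom.get(tss.chrom, ()):
            d = abs(enh.midpoint() - tss.pos)
            if d <= max_dist:
                pairs.append(CandidatePair(enh, tss, d))
    return pairs


def pairs_to_frame(pairs: Sequence[CandidatePair]) -> pd.DataFrame:
    """Tabulate pairs as the TSV interchange schema."""
    return pd.DataFrame(
        [
            (
                p.pair_id,
                p.enhancer.id,
                p.tss.gene_id,
                p.tss.chrom,
                p.distance_bp,
                p.label,
            )
            for p in pairs
        ],
        columns=["pair_id", "enhancer_id", "gene_id", "chrom", "distance_bp", "label"],
    )


def attach_labels(
    pairs: Sequence[CandidatePair], labels: dict[tuple[str, str], str]
) -> list[CandidatePair]:
    """Label pairs from a ``(enhancer_id, gene_id) -> label`` mapping."""
    out = []
    for p in pairs:
        lab = labels.get((p.enhancer.id, p.tss.gene_id))
        out.append(p.with_label(lab) if lab is not None else p)
    return out
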
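"""Synthetic test universe with a planted, dial-able interaction signal.

The generator emits an internally consistent bundle — genome annotation,
the focal cell type's two-channel 100 bp probability track, an expression
table, four cross-biosample signal panels, a cross-cell-type probability
panel, and labeled enhancer–target pairs — so the whole pipeline runs
end to end without any external download.

Signal structure for *positive* pairs mirrors the biology the features are
designed to detect: the enhancer's bins get elevated enhancer probability
and the TSS bins elevated promoter probability in the focal cell type; the
target gene is expressed; across the biosample panels, the target signal
is elevated exactly in the biosamples where the enhancer is active; the
enhancer's EP sums and the gene's PP sums co-vary across cell types; the
window between the pair is depleted of other regulatory activity (small
regulatory distance); and positive pair distances decay exponentially.
Negative pairs draw everything from the null noise model.  Setting every
effect size to zero (:meth:`SimConfig.null`) makes positives and negatives
statistically indistinguishable.

Bin probabilities are logistic transforms of Gaussian fields smoothed
along the genome, so neighbouring bins correlate the way real tracks do;
panel signals are log-normal.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activity_model import BIN_SIZE, BinTrack, read_track, write_track
from .ct_features import ExpressionTable
from .generic_features import (
    DEFAULT_PANEL_RULES,
    PANEL_KINDS,
    CrossCTPanel,
    PanelMatrix,
    activity_split,
)
from .genome_io import (
    NEGATIVE,
    POSITIVE,
    CandidatePair,
    GenomicRegion,
    TSSRecord,
    extend_to_500bp,
    read_regions,
    tss_region,
    write_regions,
    write_tss,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; effect sizes of 0 give the null model."""

    seed: int
    n_chromosomes: int = 23
    n_genes: int = 300
    enhancers_per_gene: int = 3
    n_biosamples_panel: int = 64
    n_ct_probs: int = 104
    positive_fraction: float = 0.2
    # effect sizes (0 = absent)
    ep_shift: float = 6.0  # logit boost of enhancer activity at positive elements
    pp_shift: float = 6.0  # logit boost of promoter activity at positive TSSs
    expression_shift: float = 8.0  # additive TPM shift for positive target genes
    panel_shift: float = 3.0  # multiplicative target boost in enhancer-active biosamples
    rd_suppression: float = 2.0  # logit suppression of activity in positive windows
    distance_decay: float = 100_000.0  # exponential scale of positive distances (0 = uniform)
    crossct_rho: float = 0.8  # latent correlation of EP/PP sums across cell types
    # noise / layout
    track_noise: float = 1.5
    panel_zero_inflation: float = 0.5
    gene_spacing: int = 120_000
    chrom_margin: int = 650_000
    beyond_window_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("positive_fraction", "panel_zero_inflation",
                     "beyond_window_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.crossct_rho <= 1:
            raise ValueError("crossct_rho must lie in [0, 1]")
        for name in ("ep_shift", "pp_shift", "expression_shift", "panel_shift",
                     "rd_suppression", "distance_decay", "track_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_chromosomes <= 0 or self.enhancers_per_gene <= 0:
            raise ValueError("degenerate genome layout")

    @classmethod
    def strong(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The default planted-signal regime."""
        return cls(seed=seed, **overrides)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimConfig":
        """All effect sizes off: labels carry no signal."""
        defaults = dict(
            ep_shift=0.0,
            pp_shift=0.0,
            expression_shift=0.0,
            panel_shift=0.0,
            rd_suppression=0.0,
            distance_decay=0.0,
            crossct_rho=0.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class SimBundle:
    """Everything the pipeline consumes, cross-referenced by ids."""

    config: SimConfig
    regions: list[GenomicRegion]
    tss: list[TSSRecord]
    track: BinTrack
    expression: ExpressionTable
    panels: dict[str, PanelMatrix]
    crossct: CrossCTPanel
    pairs: list[CandidatePair]
    truth: pd.DataFrame


def _smooth_field(rng: np.random.Generator, n: int, sigma: float = 3.0) -> np.ndarray:
    """Unit-variance Gaussian field with local correlation along the genome."""
    radius = int(4 * sigma)
    kernel = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    kernel /= np.sqrt((kernel**2).sum())  # keeps unit variance after convolution
    white = rng.standard_normal(n + 2 * radius)
    return np.convolve(white, kernel, mode="valid")[:n]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _bin_span(region: GenomicRegion) -> tuple[int, int]:
    """Indices (inclusive, exclusive) of grid bins overlapping a region."""
    return region.start // BIN_SIZE, -(-region.end // BIN_SIZE)


def simulate(config: SimConfig) -> SimBundle:
    """Generate a complete bundle; fully deterministic given the seed."""
    rng = np.random.default_rng(config.seed)

    # --- genome layout: genes round-robin across chromosomes -------------
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if c < config.n_genes % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    tss: list[TSSRecord] = []
    chrom_len: dict[str, int] = {}
    gi = 0
    for c, ngc in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        chrom_len[chrom] = 2 * config.chrom_margin + max(ngc, 1) * config.gene_spacing
        for j in range(ngc):
            pos = (
                config.chrom_margin
                + j * config.gene_spacing
                + int(rng.integers(0, config.gene_spacing // 4))
            )
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(TSSRecord(chrom, pos, f"G{gi:04d}", strand))
            gi += 1

    # --- designated pairs: enhancers planted around their gene -----------
    regions: list[GenomicRegion] = []
    truth_rows = []
    pairs: list[CandidatePair] = []
    eid = 0
    for t in tss:
        for _ in range(config.enhancers_per_gene):
            positive = rng.random() < config.positive_fraction
            beyond = rng.random() < config.beyond_window_fraction
            if beyond:
                d = float(rng.uniform(502_000, 560_000))
            elif positive and config.distance_decay > 0:
                d = min(5_000 + rng.exponential(config.distance_decay), 450_000.0)
            else:
                d = float(rng.uniform(5_000, 480_000))
            side = -1 if rng.random() < 0.5 else 1
            mid = t.pos + side * int(d)
            length = int(rng.integers(150, 351))
            start = max(mid - length // 2, 0)
            region = GenomicRegion(t.chrom, start, start + length, f"E{eid:05d}")
            regions.append(region)
            eid += 1
            label = POSITIVE if positive else NEGATIVE
            dist = abs(region.midpoint() - t.pos)
            in_window = dist <= 500_000
            truth_rows.append(
                (f"{region.id}--{t.gene_id}", region.id, t.gene_id, t.chrom,
                 dist, label, in_window)
            )
            if in_window:
                pairs.append(CandidatePair(region, t, dist, label))
    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "enhancer_id", "gene_id", "chrom", "distance_bp",
                 "label", "in_window"],
    )

    gene_positive: dict[str, list[GenomicRegion]] = {}
    for p in pairs:
        if p.label == POSITIVE:
            gene_positive.setdefault(p.tss.gene_id, []).append(p.enhancer)
    tss_by_gene = {t.gene_id: t for t in tss}

    # --- focal cell type bin track ---------------------------------------
    chrom_logits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in chrom_len.items():
        n_bins = -(-length // BIN_SIZE)
        logit_a = -2.5 + config.track_noise * _smooth_field(rng, n_bins)
        logit_e = 0.0 + config.track_noise * _smooth_field(rng, n_bins)
        chrom_logits[chrom] = (logit_a, logit_e)

    for p in pairs:
        if p.label != POSITIVE:
            continue
        logit_a, logit_e = chrom_logits[p.tss.chrom]
        lo, hi = _bin_span(extend_to_500bp(p.enhancer))
        logit_a[lo:hi] += config.ep_shift
        logit_e[lo:hi] += config.ep_shift
        # window depletion between the extended regions
        enh500 = extend_to_500bp(p.enhancer)
        prom500 = tss_region(p.tss)
        left, right = sorted((enh500, prom500), key=lambda r: r.start)
        w_lo = -(-left.end // BIN_SIZE)
        w_hi = right.start // BIN_SIZE
        if w_hi > w_lo:
            logit_a[w_lo:w_hi] -= config.rd_suppression
    for gene_id in gene_positive:
        t = tss_by_gene[gene_id]
        logit_a, logit_e = chrom_logits[t.chrom]
        lo, hi = _bin_span(tss_region(t))
        logit_a[lo:hi] += config.pp_shift
        logit_e[lo:hi] -= config.pp_shift

    chrom_map = {}
    for chrom, (logit_a, logit_e) in chrom_logits.items():
        starts = BIN_SIZE * np.arange(logit_a.size, dtype=np.int64)
        chrom_map[chrom] = (starts, _sigmoid(logit_a), _sigmoid(logit_e))
    track = BinTrack.from_arrays(chrom_map)

    # --- expression table -------------------------------------------------
    gene_ids = [t.gene_id for t in tss]
    base_tpm = rng.lognormal(0.0, 1.0, len(gene_ids)) * (
        rng.random(len(gene_ids)) < 0.7
    )
    boost = config.expression_shift * rng.lognormal(0.0, 0.25, len(gene_ids))
    tpm = base_tpm.copy()
    for i, g in enumerate(gene_ids):
        if g in gene_positive:
            tpm[i] = base_tpm[i] + boost[i]
    expression = ExpressionTable(pd.Series(tpm, index=gene_ids))

    # --- cross-biosample panels -------------------------------------------
    E, G, B = len(regions), len(gene_ids), config.n_biosamples_panel
    enh_ids = [r.id for r in regions]
    biosamples = [f"BS{j:03d}" for j in range(B)]
    enh_index = {r.id: i for i, r in enumerate(regions)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    cage_enh = rng.lognormal(0.0, 1.0, (E, B)) * (
        rng.random((E, B)) >= config.panel_zero_inflation
    )
    dhs_enh = rng.lognormal(0.0, 1.0, (E, B))
    crup_enh = rng.beta(2.0, 5.0, (E, B))
    if config.panel_shift > 0:
        # positive enhancers are genuinely active in a subset of biosamples
        for enhs in gene_positive.values():
            for r in enhs:
                active_ct = rng.random(B) < 0.3
                crup_enh[enh_index[r.id], active_ct] = rng.beta(
                    5.0, 2.0, int(active_ct.sum())
                )
    cage_t = rng.lognormal(0.0, 1.0, (G, B))
    dhs_t = rng.lognormal(0.0, 1.0, (G, B))
    dhsx_t = rng.lognormal(0.0, 1.0, (G, B))
    crup_t = rng.lognormal(0.0, 1.0, (G, B))

    panel_arrays = {
        "CAGE": (cage_enh, cage_t),
        "DHS": (dhs_enh, dhs_t),
        "DHS_EXPR": (dhs_enh, dhsx_t),
        "CRUP_EXPR": (crup_enh, crup_t),
    }
    if config.panel_shift > 0:
        factor = 1.0 + config.panel_shift
        for gene_id, enhs in gene_positive.items():
            lead = enhs[0]  # one planted association per gene
            g = gene_index[gene_id]
            for kind, (enh_mat, t_mat) in panel_arrays.items():
                mask = activity_split(
                    enh_mat[enh_index[lead.id]], DEFAULT_PANEL_RULES[kind]
                )
                t_mat[g, mask] *= factor

    panels = {
        kind: PanelMatrix(
            kind,
            pd.DataFrame(enh_mat, index=enh_ids, columns=biosamples),
            pd.DataFrame(t_mat, index=gene_ids, columns=biosamples),
        )
        for kind, (enh_mat, t_mat) in panel_arrays.items()
    }

    # --- cross-cell-type EP/PP sums ---------------------------------------
    C = config.n_ct_probs
    ct_ids = [f"CT{j:03d}" for j in range(C)]
    enh_ep = 1.0 + 0.5 * rng.standard_normal((E, C))
    gene_pp = 1.0 + 0.5 * rng.standard_normal((G, C))
    rho = config.crossct_rho
    if rho > 0:
        c_shared = math.sqrt(rho)
        c_noise = math.sqrt(1.0 - rho)
        for gene_id, enhs in gene_positive.items():
            a = rng.standard_normal(C)
            g = gene_index[gene_id]
            gene_pp[g] = 1.0 + 0.5 * (
                c_shared * a + c_noise * rng.standard_normal(C)
            )
            for r in enhs:
                enh_ep[enh_index[r.id]] = 1.0 + 0.5 * (
                    c_shared * a + c_noise * rng.standard_normal(C)
                )
    np.clip(enh_ep, 0.0, None, out=enh_ep)
    np.clip(gene_pp, 0.0, None, out=gene_pp)
    crossct = CrossCTPanel(
        pd.DataFrame(enh_ep, index=enh_ids, columns=ct_ids),
        pd.DataFrame(gene_pp, index=gene_ids, columns=ct_ids),
    )

    logger.info(
        "simulated %d genes, %d enhancers, %d labeled pairs (%d positive)",
        G, E, len(pairs), sum(p.label == POSITIVE for p in pairs),
    )
    return SimBundle(
        config, regions, tss, track, expression, panels, crossct, pairs, truth
    )


# ---------------------------------------------------------------------------
# bundle I/O


def write_bundle(bundle: SimBundle, directory: str | Path) -> dict:
    """Write the bundle as plain-text files plus a manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "regions": "regions.bed",
        "tss": "tss.tsv",
        "track": "track.tsv",
        "expression": "expression.tsv",
        "pairs": "pairs.tsv",
        "truth": "truth.tsv",
        "crossct_enh": "crossct_enh_ep.tsv",
        "crossct_gene": "crossct_gene_pp.tsv",
    }
    write_regions(bundle.regions, directory / files["regions"])
    write_tss(bundle.tss, directory / files["tss"])
    write_track(bundle.track, directory / files["track"])
    bundle.expression.to_tsv(directory / files["expression"])
    _pairs_frame(bundle.pairs).to_csv(directory / files["pairs"], sep="\t", index=False)
    bundle.truth.to_csv(directory / files["truth"], sep="\t", index=False)
    bundle.crossct.enh_ep_sum.to_csv(
        directory / files["crossct_enh"], sep="\t", index_label="enhancer_id"
    )
    bundle.crossct.gene_pp_sum.to_csv(
        directory / files["crossct_gene"], sep="\t", index_label="gene_id"
    )
    panel_entries = {}
    for kind, panel in bundle.panels.items():
        enh_file = f"panel_{kind}_enh.tsv"
        target_file = f"panel_{kind}_target.tsv"
        panel.enh_signal.to_csv(directory / enh_file, sep="\t", index_label="id")
        panel.target_signal.to_csv(directory / target_file, sep="\t", index_label="id")
        panel_entries[kind] = {
            "enh": enh_file,
            "target": target_file,
            "activity_rule": panel.activity_rule,
        }
    manifest = {
        "config": bundle.config.to_dict(),
        "files": files,
        "panels": panel_entries,
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _pairs_frame(pairs: list[CandidatePair]) -> pd.DataFrame:
    from .genome_io import pairs_to_frame

    return pairs_to_frame(pairs)


def read_bundle(directory: str | Path) -> SimBundle:
    """Load a bundle written by :func:`write_bundle` with zero loss."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    files = manifest["files"]
    config = SimConfig.from_dict(manifest["config"])
    regions = read_regions(directory / files["regions"])
    from .genome_io import read_tss

    tss = read_tss(directory / files["tss"])
    track = read_track(directory / files["track"])
    expression = ExpressionTable.from_tsv(directory / files["expression"])
    pairs_df = pd.read_csv(directory / files["pairs"], sep="\t")
    region_map = {r.id: r for r in regions}
    tss_map = {t.gene_id: t for t in tss}
    pairs = [
        CandidatePair(
            region_map[row.enhancer_id],
            tss_map[row.gene_id],
            int(row.distance_bp),
            str(row.label),
        )
        for row in pairs_df.itertuples()
    ]
    truth = pd.read_csv(directory / files["truth"], sep="\t")

    def _indexed(path, col):
        df = pd.read_csv(path, sep="\t", index_col=col)
        df.index.name = None
        return df

    crossct = CrossCTPanel(
        _indexed(directory / files["crossct_enh"], "enhancer_id"),
        _indexed(directory / files["crossct_gene"], "gene_id"),
    )
    panels = {}
    for kind, entry in manifest["panels"].items():
        panels[kind] = PanelMatrix(
            kind,
            _indexed(directory / entry["enh"], "id"),
            _indexed(directory / entry["target"], "id"),
            activity_rule=entry["activity_rule"],
        )
    return SimBundle(
        config, regions, tss, track, expression, panels, crossct, pairs, truth
    )
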
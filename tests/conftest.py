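import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from etpred import CandidatePair, GenomicRegion, SimConfig, TSSRecord, simulate
from etpred.genome_io import UNLABELED
from etpred.pipeline import compute_feature_table

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_pair(
    enh_mid: int,
    tss_pos: int,
    chrom: str = "chr1",
    label: str = UNLABELED,
    enh_id: str = "E1",
    gene_id: str = "G1",
    enh_len: int = 300,
) -> CandidatePair:
    """A candidate pair whose enhancer midpoint is exactly ``enh_mid``."""
    start = enh_mid - enh_len // 2
    region = GenomicRegion(chrom, start, start + enh_len, enh_id)
    tss = TSSRecord(chrom, tss_pos, gene_id)
    return CandidatePair(region, tss, abs(region.midpoint() - tss_pos), label)


@pytest.fixture(scope="session")
def small_strong_bundle():
    """A small planted-signal universe shared across tests (~140 pairs)."""
    return simulate(SimConfig.strong(seed=0, n_genes=46))


@pytest.fixture(scope="session")
def small_feature_table(small_strong_bundle):
    b = small_strong_bundle
    return compute_feature_table(b.pairs, b.track, b.expression, b.panels, b.crossct)
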
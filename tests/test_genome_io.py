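import numpy as np
import pytest

from etpred.genome_io import (
    CandidatePair,
    GenomicRegion,
    ParseError,
    TSSRecord,
    enumerate_candidates,
    extend_to_500bp,
    midpoint,
    read_regions,
    read_tss,
    tss_region,
    write_regions,
)


class TestRegions:
    def test_bed_line_parsed_with_id(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t999\t1349\tEH38E0001\n")
        (region,) = read_regions(p)
        assert region == GenomicRegion("chr1", 999, 1349, "EH38E0001")

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("")
        assert read_regions(p) == []

    @pytest.mark.parametrize(
        "line", ["chr1\t500\t400", "chr1\tx\t400", "chr1\t500", "chr1\t-5\t400"]
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t100\tok\n" + line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_regions(p)

    def test_id_synthesized_from_coordinates(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr2\t10\t60\n")
        (region,) = read_regions(p)
        assert region.id == "chr2:10-60"

    def test_roundtrip_preserves_coordinates_and_ids(self, tmp_path):
        rng = np.random.default_rng(7)
        regions = []
        for i in range(50):
            start = int(rng.integers(0, 10_000))
            regions.append(
                GenomicRegion(f"chr{rng.integers(1, 5)}", start,
                              start + int(rng.integers(1, 500)), f"E{i}")
            )
        path = tmp_path / "out.bed"
        write_regions(regions, path)
        assert read_regions(path) == regions


class TestMidpointAndExtension:
    @pytest.mark.parametrize(
        "start,end,mid", [(1000, 1350, 1175), (0, 1, 0), (10, 13, 11)]
    )
    def test_midpoint_floor_rule(self, start, end, mid):
        assert midpoint(GenomicRegion("chr1", start, end)) == mid

    @pytest.mark.parametrize(
        "start,end,expected",
        [(1000, 1286, (893, 1393)), (100, 600, (100, 600))],
    )
    def test_extension_centres_on_midpoint(self, start, end, expected):
        ext = extend_to_500bp(GenomicRegion("chr1", start, end, "E"))
        assert (ext.start, ext.end) == expected
        assert ext.length == 500

    def test_extension_clamped_at_chromosome_origin(self):
        ext = extend_to_500bp(GenomicRegion("chr1", 10, 20, "E"))
        assert (ext.start, ext.end) == (0, 500)

    def test_tss_window_centred_on_position(self):
        reg = tss_region(TSSRecord("chr1", 1000, "G1"))
        assert (reg.start, reg.end) == (750, 1250)


class TestTSSParsing:
    def _gtf(self, tmp_path, body):
        p = tmp_path / "a.gtf"
        p.write_text(body)
        return p

    def test_gene_line_plus_strand(self, tmp_path):
        p = self._gtf(
            tmp_path,
            'chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tgene_id "G1";\n',
        )
        (rec,) = read_tss(p)
        assert rec == TSSRecord("chr1", 999, "G1", "+")

    def test_gene_line_minus_strand(self, tmp_path):
        p = self._gtf(
            tmp_path,
            'chr1\tsrc\tgene\t1000\t2000\t.\t-\t.\tgene_id "G1";\n',
        )
        (rec,) = read_tss(p)
        assert rec.pos == 1999

    def test_transcripts_collapse_to_five_prime_most(self, tmp_path):
        p = self._gtf(
            tmp_path,
            'chr1\tsrc\ttranscript\t1000\t2000\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\ttranscript\t1500\t2500\t.\t+\t.\tgene_id "G1";\n',
        )
        (rec,) = read_tss(p)
        assert rec.pos == 999
        both = read_tss(p, collapse=False)
        assert [r.pos for r in both] == [999, 1499]

    def test_missing_gene_id_raises(self, tmp_path):
        p = self._gtf(
            tmp_path, 'chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tother "x";\n'
        )
        with pytest.raises(ParseError, match="gene_id"):
            read_tss(p)


class TestCandidateEnumeration:
    def test_distance_window_is_inclusive(self):
        tss = [TSSRecord("chr1", 1_000_000, "G1")]
        mk = lambda mid, eid: GenomicRegion("chr1", mid - 150, mid + 150, eid)
        enh = [mk(1_400_000, "in"), mk(1_500_000, "edge"), mk(1_500_001, "out")]
        pairs = enumerate_candidates(tss, enh)
        assert [p.enhancer.id for p in pairs] == ["in", "edge"]
        assert pairs[0].distance_bp == 400_000

    def test_other_chromosome_excluded(self):
        tss = [TSSRecord("chr1", 1000, "G1")]
        enh = [GenomicRegion("chr2", 900, 1200, "E1")]
        assert enumerate_candidates(tss, enh) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tss = [
                TSSRecord(f"chr{rng.integers(1, 4)}", int(rng.integers(0, 2_000_000)),
                          f"G{i}")
                for i in range(15)
            ]
            enh = []
            for i in range(30):
                start = int(rng.integers(0, 2_000_000))
                enh.append(
                    GenomicRegion(f"chr{rng.integers(1, 4)}", start, start + 200,
                                  f"E{i}")
                )
            got = {(p.enhancer.id, p.tss.gene_id) for p in enumerate_candidates(tss, enh)}
            expected = {
                (e.id, t.gene_id)
                for t in tss
                for e in enh
                if e.chrom == t.chrom and abs(e.midpoint() - t.pos) <= 500_000
            }
            assert got == expected

    def test_output_pairs_satisfy_invariants(self):
        rng = np.random.default_rng(11)
        tss = [TSSRecord("chr1", int(rng.integers(0, 3_000_000)), f"G{i}")
               for i in range(10)]
        enh = [GenomicRegion("chr1", s := int(rng.integers(0, 3_000_000)), s + 300,
                             f"E{i}") for i in range(20)]
        for p in enumerate_candidates(tss, enh):
            assert p.distance_bp <= 500_000
            assert p.enhancer.chrom == p.tss.chrom


class TestInvariants:
    def test_region_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            GenomicRegion("chr1", 500, 400)

    def test_pair_rejects_cross_chromosome(self):
        enh = GenomicRegion("chr1", 0, 300, "E1")
        with pytest.raises(ValueError):
            CandidatePair(enh, TSSRecord("chr2", 1000, "G1"), 850)

    def test_pair_rejects_wrong_distance(self):
        enh = GenomicRegion("chr1", 0, 300, "E1")
        with pytest.raises(ValueError):
            CandidatePair(enh, TSSRecord("chr1", 1000, "G1"), 851)
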
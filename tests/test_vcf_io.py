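"""Decoding the three VCF SV notations and writing ranked output."""

import pytest

from svprio import (
    Contig,
    GenomicRegion,
    HarmonizedVariant,
    Strand,
    SvType,
    read_vcf,
    write_results,
)
from svprio.prioritization import psv_score, rank_variants

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="x">
##INFO=<ID=RE,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(tmp_path, *records):
    path = tmp_path / "in.vcf"
    path.write_text(HEADER + "".join(r + "\n" for r in records))
    return path


class TestSequenceNotation:
    def test_deletion_coordinates(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\td1\tACGT\tA\t.\tPASS\t.\tGT\t0/1")
        (v,) = read_vcf(path).variants
        assert v.sv_type is SvType.DEL
        # bases 101..103 (1-based) are deleted -> [100, 103) internally
        assert (v.region.start, v.region.end) == (100, 103)

    def test_insertion_anchor_and_length(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\ti1\tA\tACGTCG\t.\tPASS\t.\tGT\t0/1")
        (v,) = read_vcf(path).variants
        assert v.sv_type is SvType.INS
        assert (v.region.start, len(v.region), v.ins_length) == (100, 0, 5)

    def test_snv_is_skipped_and_counted(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\ts1\tA\tC\t.\tPASS\t.\tGT\t0/1")
        result = read_vcf(path)
        assert result.variants == [] and len(result.skipped) == 1
        assert result.n_records == 1


class TestSymbolicNotation:
    def test_inversion_with_end(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t100\tv1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=200\tGT\t0/1"
        )
        (v,) = read_vcf(path).variants
        # [100, 200] 1-based inclusive -> [99, 200) internal
        assert v.sv_type is SvType.INV
        assert (v.region.start, v.region.end) == (99, 200)

    def test_deletion_with_svlen_only(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t100\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-50\tGT\t0/1"
        )
        (v,) = read_vcf(path).variants
        # SVLEN fixes the length: 50 deleted bases from POS
        assert (v.region.start, v.region.end) == (99, 149)

    def test_symbolic_without_end_or_svlen_is_skipped(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL\tGT\t0/1")
        result = read_vcf(path)
        assert result.variants == []
        assert "END" in result.skipped[0][1] or "SVLEN" in result.skipped[0][1]

    def test_insertion_symbolic(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t500\tv1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=120\tGT\t0/1"
        )
        (v,) = read_vcf(path).variants
        assert (v.region.start, v.ins_length) == (500, 120)


class TestBreakendNotation:
    def test_right_facing_adjacency(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t100\tb1\tA\tA[chr2:321682[\t.\tPASS\tSVTYPE=BND\tGT\t0/1"
        )
        (v,) = read_vcf(path).variants
        adj = v.adjacency
        assert v.sv_type is SvType.BND
        assert (adj.left.contig.name, adj.left.position + 1) == ("chr1", 100)
        assert (adj.right.contig.name, adj.right.position + 1) == ("chr2", 321682)
        assert adj.left.strand is Strand.POS and adj.right.strand is Strand.POS

    def test_reverse_orientation_brackets(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t100\tb1\tA\t]chr2:500]A\t.\tPASS\tSVTYPE=BND\tGT\t0/1"
        )
        (v,) = read_vcf(path).variants
        assert v.adjacency.left.strand is Strand.NEG
        assert v.adjacency.right.strand is Strand.NEG

    def test_malformed_bracket_alt_is_skipped(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t100\tb1\tA\tA[chr2:xx[\t.\tPASS\tSVTYPE=BND\tGT\t0/1"
        )
        result = read_vcf(path)
        assert result.variants == [] and len(result.skipped) == 1


class TestAltDepth:
    def test_pbsv_uses_second_ad_entry(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\tGT:AD\t0/1:5,7",
        )
        (v,) = read_vcf(path, dialect="pbsv").variants
        assert v.alt_read_count == 7

    def test_svim_uses_info_support(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200;SUPPORT=9\tGT\t0/1",
        )
        (v,) = read_vcf(path, dialect="svim").variants
        assert v.alt_read_count == 9

    def test_sniffles_dv_with_re_fallback(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "chr1\t100\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\tGT:DV\t0/1:11",
            "chr1\t300\tv2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=400;RE=4\tGT\t0/1",
        )
        v1, v2 = read_vcf(path, dialect="sniffles").variants
        assert (v1.alt_read_count, v2.alt_read_count) == (11, 4)

    def test_absent_depth_is_unknown_and_variant_kept(self, tmp_path):
        path = write_vcf(
            tmp_path, "chr1\t100\tv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\tGT\t0/1"
        )
        result = read_vcf(path, dialect="auto")
        assert result.variants[0].alt_read_count is None


class TestWriteResults:
    CONTIG = Contig("chr1", 1_000_000)

    def _scored(self, variants):
        return rank_variants([psv_score(v, []) for v in variants])

    def test_empty_list_writes_header_only_tsv(self, tmp_path):
        write_results([], tmp_path / "o.tsv", tmp_path / "o.vcf",
                      {"chr1": self.CONTIG})
        lines = (tmp_path / "o.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("rank\t")

    def test_single_variant_gets_rank_one(self, tmp_path):
        v = HarmonizedVariant(
            "v1", SvType.DEL, region=GenomicRegion(self.CONTIG, 100, 200)
        )
        write_results(self._scored([v]), tmp_path / "o.tsv", tmp_path / "o.vcf")
        rows = (tmp_path / "o.tsv").read_text().splitlines()
        assert rows[1].split("\t")[0] == "1"

    @pytest.mark.parametrize(
        "variant",
        [
            HarmonizedVariant("d", SvType.DEL,
                              region=GenomicRegion(CONTIG, 100, 250)),
            HarmonizedVariant("u", SvType.DUP,
                              region=GenomicRegion(CONTIG, 5_000, 9_000),
                              copy_number_gain=2),
            HarmonizedVariant("n", SvType.INV,
                              region=GenomicRegion(CONTIG, 700, 1_400)),
            HarmonizedVariant("i", SvType.INS,
                              region=GenomicRegion(CONTIG, 333, 333), ins_length=80),
        ],
        ids=["DEL", "DUP", "INV", "INS"],
    )
    def test_round_trip_preserves_coordinates(self, tmp_path, variant):
        write_results(
            self._scored([variant]), tmp_path / "o.tsv", tmp_path / "o.vcf"
        )
        (back,) = read_vcf(tmp_path / "o.vcf").variants
        assert back.sv_type is variant.sv_type
        assert (back.region.start, back.region.end) == (
            variant.region.start, variant.region.end,
        )
        assert back.ins_length == variant.ins_length
        assert back.copy_number_gain == variant.copy_number_gain
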
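"""Transcript loading, UTR derivation, promoters, and gene lookup."""

import json
import random

import pytest

from svprio import (
    Contig,
    GeneIndex,
    GenomicRegion,
    HarmonizedVariant,
    Strand,
    SvType,
    Transcript,
    load_transcripts,
    overlaps,
    promoter_of,
)


def make_json(tmp_path, genes, contigs=(("chr1", 1_000_000),)):
    obj = {
        "contigs": [{"name": n, "length": l} for n, l in contigs],
        "genes": genes,
    }
    path = tmp_path / "tx.json"
    path.write_text(json.dumps(obj))
    return path


class TestLoading:
    def test_single_exon_cds_equals_exon_has_no_utrs(self, tmp_path):
        path = make_json(tmp_path, [{
            "gene_id": "A", "transcripts": [{
                "tx_id": "A.t1", "contig": "chr1", "strand": "+",
                "exons": [[1000, 1600]], "cds": [1000, 1600]}],
        }])
        (gene,) = load_transcripts(path)
        tx = gene.transcripts[0]
        assert tx.utr5_length() == 0 and tx.utr3_length() == 0

    def test_utr5_length_equals_cds_offset_in_first_exon(self, tmp_path):
        path = make_json(tmp_path, [{
            "gene_id": "A", "transcripts": [{
                "tx_id": "A.t1", "contig": "chr1", "strand": "+",
                "exons": [[1000, 1300], [2000, 2200], [3000, 3500]],
                "cds": [1070, 3400]}],
        }])
        (gene,) = load_transcripts(path)
        tx = gene.transcripts[0]
        assert tx.utr5_length() == 70  # offset of the CDS into exon 1
        assert tx.utr3_length() == 100

    def test_noncoding_transcript_has_no_cds_and_no_utrs(self, tmp_path):
        path = make_json(tmp_path, [{
            "gene_id": "N", "transcripts": [{
                "tx_id": "N.t1", "contig": "chr1", "strand": "-",
                "exons": [[5000, 6000]], "cds": None}],
        }])
        (gene,) = load_transcripts(path)
        tx = gene.transcripts[0]
        assert not tx.is_coding
        assert tx.utr5_regions() == [] and tx.coding_regions() == []

    def test_cds_outside_span_rejected_naming_the_transcript(self, tmp_path):
        path = make_json(tmp_path, [{
            "gene_id": "B", "transcripts": [{
                "tx_id": "B.bad", "contig": "chr1", "strand": "+",
                "exons": [[1000, 2000]], "cds": [500, 1500]}],
        }])
        with pytest.raises(ValueError, match="B.bad"):
            load_transcripts(path)

    def test_gff3_agrees_with_json_dialect(self, tmp_path):
        gff = tmp_path / "tx.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "##sequence-region chr1 1 1000000\n"
            "chr1\tsrc\tgene\t1001\t3500\t.\t+\t.\tID=A;Name=GENEA\n"
            "chr1\tsrc\tmRNA\t1001\t3500\t.\t+\t.\tID=A.t1;Parent=A\n"
            "chr1\tsrc\texon\t1001\t1300\t.\t+\t.\tParent=A.t1\n"
            "chr1\tsrc\texon\t2001\t2200\t.\t+\t.\tParent=A.t1\n"
            "chr1\tsrc\texon\t3001\t3500\t.\t+\t.\tParent=A.t1\n"
            "chr1\tsrc\tCDS\t1071\t1300\t.\t+\t0\tParent=A.t1\n"
            "chr1\tsrc\tCDS\t2001\t2200\t.\t+\t1\tParent=A.t1\n"
            "chr1\tsrc\tCDS\t3001\t3400\t.\t+\t0\tParent=A.t1\n"
        )
        (gene,) = load_transcripts(gff)
        tx = gene.transcripts[0]
        assert gene.symbol == "GENEA"
        assert (tx.region.start, tx.region.end) == (1000, 3500)
        assert (tx.cds_start, tx.cds_end) == (1070, 3400)
        assert tx.utr5_length() == 70 and tx.utr3_length() == 100


class TestPromoter:
    CONTIG = Contig("chr1", 100_000)

    def tx(self, start, end, strand):
        region = GenomicRegion(self.CONTIG, start, end, strand)
        return Transcript("t", "g", region, (region,))

    def test_plus_strand(self):
        p = promoter_of(self.tx(10_000, 20_000, Strand.POS))
        assert (p.region.start, p.region.end) == (8_000, 10_000)

    def test_minus_strand_mirrors_downstream(self):
        p = promoter_of(self.tx(5_000, 10_000, Strand.NEG))
        assert (p.region.start, p.region.end) == (10_000, 12_000)

    def test_clipped_at_contig_start(self):
        p = promoter_of(self.tx(500, 2_000, Strand.POS))
        assert (p.region.start, p.region.end) == (0, 500)


def test_utr_cds_partition_exonic_length(world):
    """UTR5 + CDS + UTR3 exonic bases account for every exonic base."""
    for gene in world.genes:
        for tx in gene.transcripts:
            if not tx.is_coding:
                continue
            exonic = sum(len(e) for e in tx.exons)
            coding = sum(len(r) for r in tx.coding_regions())
            assert tx.utr5_length() + coding + tx.utr3_length() == exonic


class TestGenesForVariant:
    def var(self, world, start, end, sv_type=SvType.DEL, contig="chr1"):
        region = GenomicRegion(world.contigs[contig], start, end)
        if sv_type is SvType.INS:
            return HarmonizedVariant(
                "v", sv_type, region=GenomicRegion(world.contigs[contig], start, start),
                ins_length=100,
            )
        return HarmonizedVariant("v", sv_type, region=region)

    def test_intronic_deletion_hits_its_gene_only(self, world):
        index = GeneIndex(world.genes)
        genes = index.genes_for_variant(self.var(world, 101_000, 101_500))
        assert [g.gene_id for g in genes] == ["G01"]

    def test_deletion_spanning_two_genes(self, world):
        index = GeneIndex(world.genes)
        genes = index.genes_for_variant(self.var(world, 99_000, 135_000, contig="chr3"))
        assert [g.gene_id for g in genes] == ["G11", "G12"]

    def test_intergenic_insertion_returns_flanking_genes(self, world):
        # between G11 (ends 110000) and G12 (starts 120000) on chr3,
        # outside G12's promoter
        index = GeneIndex(world.genes)
        genes = index.genes_for_variant(
            self.var(world, 114_000, 114_000, SvType.INS, contig="chr3")
        )
        assert {g.gene_id for g in genes} == {"G11", "G12"}

    def test_gene_free_contig_yields_empty_set(self, world):
        index = GeneIndex([g for g in world.genes if g.contig.name != "chr2"])
        assert index.genes_for_variant(self.var(world, 1000, 2000, contig="chr2")) == []

    def test_index_agrees_with_linear_scan(self, world):
        """Interval-index lookups match a brute-force transcript scan."""
        index = GeneIndex(world.genes)
        rng = random.Random(7)
        for _ in range(100):
            contig = rng.choice(list(world.contigs.values()))
            start = rng.randrange(0, contig.length - 10_000)
            v = HarmonizedVariant(
                "v", SvType.DEL,
                region=GenomicRegion(contig, start, start + rng.randint(1, 8_000)),
            )
            expected = set()
            for g in world.genes:
                if g.contig.name != contig.name:
                    continue
                for tx in g.transcripts:
                    if overlaps(v.region, tx.region) or overlaps(
                        v.region, promoter_of(tx).region
                    ):
                        expected.add(g.gene_id)
            got = {g.gene_id for g in index._hits(v.region)}
            assert got == expected
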
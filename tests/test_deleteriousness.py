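"""δ(g) scoring rules for every SV class and overlap category.

The toy gene G01 spans chr1:100000-110000 with exons at +0..300
(100-bp 5'UTR), +5000..5144 (a 144-bp in-frame coding exon), and
+9000..10000 (CDS ends at +9800, leaving a 200-bp 3'UTR).
"""

import pytest

from svprio import (
    Adjacency,
    Breakend,
    Element,
    FrameEffect,
    GenomicRegion,
    HarmonizedVariant,
    OverlapContext,
    Relationship,
    Strand,
    SvType,
    classify_overlap,
    delta_breakend,
    delta_deletion,
    delta_duplication,
    delta_insertion,
    delta_inversion,
    gene_delta,
)

S = 100_000  # G01 gene start


def make_variant(world, sv_type, start, end, ins_length=0, gain=1, contig="chr1"):
    c = world.contigs[contig]
    if sv_type is SvType.INS:
        return HarmonizedVariant(
            "v", sv_type, region=GenomicRegion(c, start, start),
            ins_length=ins_length,
        )
    return HarmonizedVariant(
        "v", sv_type, region=GenomicRegion(c, start, end), copy_number_gain=gain
    )


def bnd_at(world, pos, contig="chr1", mate=("chr2", 500)):
    c = world.contigs[contig]
    m = world.contigs[mate[0]]
    return HarmonizedVariant(
        "b", SvType.BND,
        adjacency=Adjacency(
            Breakend(c, pos, Strand.POS), Breakend(m, mate[1], Strand.POS)
        ),
    )


class TestTableCells:
    """Every (SV class x overlap category) scoring cell on a real fixture."""

    @pytest.mark.parametrize(
        "sv_type,start,end,kw,expected",
        [
            # --- deletions ---
            (SvType.DEL, S - 500, S + 11_000, {}, 1.0),  # t in SV
            (SvType.DEL, S + 5_050, S + 9_100, {}, 1.0),  # frameshift, multi-element
            (SvType.DEL, S + 4_990, S + 5_154, {}, 0.8),  # whole 144-bp exon, in-frame
            (SvType.DEL, S + 5_010, S + 5_043, {}, 0.8),  # 33 coding bases, in-frame
            (SvType.DEL, S + 5_010, S + 5_042, {}, 1.0),  # 32 coding bases: frameshift
            (SvType.DEL, S + 10, S + 35, {}, 0.5),  # 25 of 100 UTR5 bases: 2*25/100
            (SvType.DEL, S + 9_800, S + 9_900, {}, 1.0),  # 100 of 200 UTR3 bases
            (SvType.DEL, S + 1_000, S + 1_500, {}, 0.0),  # deep intronic
            (SvType.DEL, S - 1_500, S - 500, {}, 0.4),  # promoter-contained
            (SvType.DEL, S - 50, S + 50, {}, 1.0),  # removes the TSS
            # --- duplications ---
            (SvType.DUP, S - 100, S + 10_100, {}, 1.0),  # whole gene, single gain
            (SvType.DUP, S - 100, S + 10_100, {"gain": 2}, 2.0),  # triplication
            (SvType.DUP, S + 9_500, S + 10_500, {}, 0.0),  # tandem, beyond 3' end
            (SvType.DUP, S - 300, S + 400, {}, 0.0),  # tandem, beyond 5' end
            (SvType.DUP, S + 5_010, S + 5_046, {}, 1.0),  # intra-exonic coding
            (SvType.DUP, S + 1_000, S + 2_000, {}, 0.0),  # intronic
            (SvType.DUP, S - 1_500, S - 500, {}, 0.4),  # promoter
            # --- inversions ---
            (SvType.INV, S - 500, S + 11_000, {}, 0.0),  # contains transcript: neutral
            (SvType.INV, S - 500, S + 200, {}, 1.0),  # breakend inside transcript
            (SvType.INV, S + 4_000, S + 6_000, {}, 1.0),  # covers exon 2, not all
            (SvType.INV, S + 5_010, S + 5_100, {}, 1.0),  # within a coding exon
            (SvType.INV, S + 1_000, S + 2_000, {}, 0.0),  # within an intron
            (SvType.INV, S - 1_500, S - 500, {}, 0.4),  # within the promoter
        ],
    )
    def test_region_classes(self, world, g01, sv_type, start, end, kw, expected):
        v = make_variant(world, sv_type, start, end, **kw)
        assert gene_delta(v, g01).delta == pytest.approx(expected)

    @pytest.mark.parametrize(
        "point,length,expected",
        [
            (S + 5_050, 35, 0.9),  # coding frameshift
            (S + 5_050, 36, 0.2),  # coding in-frame (a 36-bp intra-exon event)
            (S + 50, 100, 1.0),  # 100 bp into the 100-bp 5'UTR: full score
            (S + 9_900, 50, 0.25),  # 50 bp into the 200-bp 3'UTR
            (S - 1_000, 50, 0.4),  # promoter
            (S + 1_000, 50, 0.0),  # intronic
            (S - 30_000, 50, 0.0),  # intergenic, outside the promoter
        ],
    )
    def test_insertions(self, world, g01, point, length, expected):
        v = make_variant(world, SvType.INS, point, point, ins_length=length)
        assert gene_delta(v, g01).delta == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (S + 5_050, 1.0),  # breakend in a coding exon
            (S + 1_000, 1.0),  # breakend in an intron
            (S + 9_900, 1.0),  # breakend in the 3'UTR
            (S - 1_000, 0.4),  # breakend in the promoter
            (S - 30_000, 0.0),  # intergenic breakend
        ],
    )
    def test_breakends(self, world, g01, pos, expected):
        assert gene_delta(bnd_at(world, pos), g01).delta == pytest.approx(expected)

    def test_both_breakends_are_scored(self, world, g01):
        v = bnd_at(world, 50_000, mate=("chr1", S + 5_050))
        assert gene_delta(v, g01).delta == 1.0


class TestClassification:
    def test_whole_transcript_deletion(self, world, g01):
        v = make_variant(world, SvType.DEL, S - 1_000, S + 11_000)
        ctx = classify_overlap(v, g01.transcripts[0])
        assert ctx.relationship is Relationship.VARIANT_CONTAINS_TRANSCRIPT

    def test_intronic_deletion_is_sv_within_element(self, world, g01):
        v = make_variant(world, SvType.DEL, S + 1_000, S + 1_500)
        ctx = classify_overlap(v, g01.transcripts[0])
        assert ctx.relationship is Relationship.VARIANT_WITHIN_ELEMENT
        assert ctx.element is Element.INTRON

    def test_whole_exon_in_frame_deletion(self, world, g01):
        """A deletion of one entire 144-bp coding exon keeps the frame."""
        v = make_variant(world, SvType.DEL, S + 4_990, S + 5_154)
        ctx = classify_overlap(v, g01.transcripts[0])
        assert ctx.element is Element.CODING_OR_SPLICE
        assert ctx.frame_effect is FrameEffect.IN_FRAME

    def test_splice_region_only_deletion_is_frameshift_equivalent(self, world, g01):
        # removes the donor dinucleotide of intron 1 but no coding base
        v = make_variant(world, SvType.DEL, S + 300, S + 302)
        ctx = classify_overlap(v, g01.transcripts[0])
        assert ctx.element is Element.CODING_OR_SPLICE
        assert delta_deletion(ctx) == 1.0

    def test_precedence_coding_beats_promoter(self, world, g01):
        """A variant touching promoter and coding scores as coding."""
        v = make_variant(world, SvType.DEL, S - 1_000, S + 150)
        ctx = classify_overlap(v, g01.transcripts[0])
        assert ctx.element is Element.CODING_OR_SPLICE
        assert delta_deletion(ctx) == 1.0

    def test_minus_strand_gene_promoter_side(self, world):
        g03 = world.gene("G03")  # minus strand: promoter downstream in coords
        v = make_variant(world, SvType.DEL, 310_500, 311_000)
        assert gene_delta(v, g03).delta == 0.4

    def test_insertion_on_splice_boundary_scores_frameshift(self, world, g01):
        v = make_variant(world, SvType.INS, S + 5_145, S + 5_145, ins_length=36)
        assert gene_delta(v, g01).delta == 0.9


class TestGeneLevel:
    def test_gene_delta_takes_max_over_transcripts(self, world):
        g02 = world.gene("G02")  # has an exon2-skipping second isoform
        v = make_variant(world, SvType.DEL, 204_990, 205_154)
        score = gene_delta(v, g02)
        assert score.per_transcript["G02.t1"][0] == 0.8
        assert score.per_transcript["G02.t2"][0] == 0.0  # intronic for the isoform
        assert score.delta == 0.8

    def test_untouched_gene_scores_zero(self, world, g01):
        v = make_variant(world, SvType.DEL, 150_000, 151_000)
        assert gene_delta(v, g01).delta == 0.0


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [1, 2, 5])
    def test_utr_formulas_depend_only_on_the_ratio(self, scale):
        del_ctx = OverlapContext(
            Relationship.VARIANT_WITHIN_ELEMENT, Element.UTR3,
            len_sv=25 * scale, len_utr=100 * scale,
        )
        ins_ctx = OverlapContext(
            Relationship.VARIANT_WITHIN_ELEMENT, Element.UTR3,
            len_ins=30 * scale, len_utr=120 * scale,
        )
        assert delta_deletion(del_ctx) == pytest.approx(0.5)
        assert delta_insertion(ins_ctx) == pytest.approx(0.25)

    def test_utr_scores_cap_at_one(self):
        ctx = OverlapContext(
            Relationship.VARIANT_WITHIN_ELEMENT, Element.UTR5,
            len_sv=90, len_utr=100,
        )
        assert delta_deletion(ctx) == 1.0  # 2*90/100 capped
        ins = OverlapContext(
            Relationship.VARIANT_WITHIN_ELEMENT, Element.UTR5,
            len_ins=250, len_utr=100,
        )
        assert delta_insertion(ins) == 1.0

    def test_delta_zero_when_element_none(self):
        ctx = OverlapContext(Relationship.VARIANT_WITHIN_ELEMENT, Element.NONE)
        assert delta_deletion(ctx) == 0.0
        assert delta_duplication(ctx, 3) == 0.0
        assert delta_inversion(ctx) == 0.0
        assert delta_insertion(ctx) == 0.0
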
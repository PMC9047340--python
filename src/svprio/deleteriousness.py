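"""Per-gene sequence deleteriousness δ(g) for each SV class.

The score is a heuristic on a [0, 1] scale (copy-number gains may exceed
1): δ(g) = 0 for presumed-neutral variants, 1 for variants predicted to
abolish transcript function.  Each SV class has its own rule set over
the relationship between the variant and a transcript:

==========  =========  =========  ====================================
SV class    t ⊂ SV     t ⇌ SV     SV ⊂ element
                                  coding/splice  UTR      intron  prom.
==========  =========  =========  =============  =======  ======  =====
DEL         1          1          {0.8, 1}       ≤ 1      0       0.4
DUP         gain       0          1              ≤ 1      0       0.4
INV         0          1          1              ≤ 1      0       0.4
INS         –          –          {0.2, 0.9}     ≤ 1      0       0.4
BND         –          –          1              1        1       0.4
==========  =========  =========  =============  =======  ======  =====

{in-frame, frameshift} pairs are resolved by the deleted/inserted coding
length modulo 3.  UTR scores grow with the affected fraction of the UTR:
deletions score min(2·len_SV/len_UTR, 1) and insertions
min(len_INS/len_UTR, 1).  Loss of the transcription start site is as
deleterious as a coding hit.  A variant touching several element classes
receives the most deleterious applicable score (precedence
coding/splice > TSS > UTR > promoter > intron).  The gene score is the
maximum over its transcripts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .annotations import GeneModel, PromoterRegion, Transcript, promoter_of
from .genome import (
    Adjacency,
    GenomicRegion,
    HarmonizedVariant,
    SvType,
    overlaps,
)

DELTA_PROMOTER = 0.4  # promoter hits score 40% of a coding hit
DELTA_INFRAME_EXON_DEL = 0.8
DELTA_FRAMESHIFT_INS = 0.9
DELTA_INFRAME_INS = 0.2
DEFAULT_SPLICE_WIDTH = 2


class Relationship(str, enum.Enum):
    VARIANT_CONTAINS_TRANSCRIPT = "t_in_sv"
    PARTIAL_OVERLAP = "partial"
    VARIANT_WITHIN_ELEMENT = "sv_in_element"


class Element(str, enum.Enum):
    CODING_OR_SPLICE = "coding_or_splice"
    TSS = "tss"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRON = "intron"
    PROMOTER = "promoter"
    NONE = "none"


class FrameEffect(str, enum.Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    NA = "n/a"


@dataclass(frozen=True)
class OverlapContext:
    """The classified relationship between one variant and one transcript."""

    relationship: Relationship
    element: Element
    frame_effect: FrameEffect = FrameEffect.NA
    len_sv: int = 0
    len_utr: int = 0
    len_ins: int = 0
    extends_beyond_terminus: bool = False
    covers_tss: bool = False


@dataclass
class DeltaScore:
    """δ(g): the maximum per-transcript deleteriousness for one gene."""

    gene_id: str
    delta: float
    per_transcript: dict[str, tuple[float, OverlapContext]] = field(
        default_factory=dict
    )


_NEUTRAL = OverlapContext(Relationship.VARIANT_WITHIN_ELEMENT, Element.NONE)


def _any_overlap(region: GenomicRegion, pieces: list[GenomicRegion]) -> int:
    return sum(region.intersection_length(p) for p in pieces)


def _point_in_any(pos: int, pieces: list[GenomicRegion]) -> bool:
    return any(p.contains_point(pos) for p in pieces)


def _touches(region: GenomicRegion, tx: Transcript, prom: PromoterRegion) -> bool:
    if len(region) == 0:
        return tx.region.contains_point(region.start) or prom.region.contains_point(
            region.start
        )
    return overlaps(region, tx.region) or overlaps(region, prom.region)


def _pick_utr(region: GenomicRegion, tx: Transcript) -> Optional[tuple[Element, int, int]]:
    """(element, overlap bases, UTR length) of the worse-affected UTR, if any."""
    best = None
    for elem, pieces in (
        (Element.UTR5, tx.utr5_regions()),
        (Element.UTR3, tx.utr3_regions()),
    ):
        total = sum(len(p) for p in pieces)
        ov = _any_overlap(region, pieces)
        if ov > 0 and total > 0:
            ratio = ov / total
            if best is None or ratio > best[3]:
                best = (elem, ov, total, ratio)
    if best is None:
        return None
    return best[0], best[1], best[2]


def _deletion_frame(region: GenomicRegion, tx: Transcript,
                    splice_width: int) -> FrameEffect:
    """Frame effect of a deletion touching coding sequence or splice regions.

    Whole-exon removals and deletions confined to one exon's coding part
    shift the frame iff the deleted coding length is not a multiple of 3;
    deletions that break a splice junction asymmetrically (part of an
    exon plus flanking intron) are frameshift-equivalent.
    """
    coding = tx.coding_regions()
    deleted = sum(region.intersection_length(c) for c in coding)
    affected = [e for e in tx.exons_forward() if region.intersection_length(e) > 0]
    if not affected:
        return FrameEffect.FRAMESHIFT  # splice-region-only hit
    if all(region.contains(e) for e in affected):
        return FrameEffect.IN_FRAME if deleted % 3 == 0 else FrameEffect.FRAMESHIFT
    if len(affected) == 1 and affected[0].contains(region):
        return FrameEffect.IN_FRAME if deleted % 3 == 0 else FrameEffect.FRAMESHIFT
    return FrameEffect.FRAMESHIFT


def classify_overlap(
    v: HarmonizedVariant,
    tx: Transcript,
    promoter: Optional[PromoterRegion] = None,
    splice_width: int = DEFAULT_SPLICE_WIDTH,
) -> OverlapContext:
    """Classify which scoring rule applies to a (variant, transcript) pair.

    Element classes compete by precedence (coding/splice > TSS > UTR >
    promoter > intron): the most deleterious wins.
    """
    if v.sv_type is SvType.BND:
        raise ValueError("breakend variants are classified per breakend")
    if promoter is None:
        promoter = promoter_of(tx)
    region = v.region
    assert region is not None
    if not _touches(region, tx, promoter):
        return _NEUTRAL
    if region.contains(tx.region):
        return OverlapContext(
            Relationship.VARIANT_CONTAINS_TRANSCRIPT,
            Element.CODING_OR_SPLICE,
            len_sv=len(region),
            covers_tss=True,
        )

    if v.sv_type is SvType.INS:
        return _classify_insertion(v, tx, promoter, splice_width)

    partial = overlaps(region, tx.region) and not tx.region.contains(region)
    beyond = partial and (
        region.start < tx.region.start or region.end > tx.region.end
    )
    covers_tss = region.contains_point(tx.tss)

    coding_hit = _any_overlap(region, tx.coding_regions()) > 0 or _any_overlap(
        region, tx.splice_regions(splice_width)
    ) > 0
    if not tx.is_coding and _any_overlap(region, list(tx.exons)) > 0:
        coding_hit = True  # exon of a non-coding transcript: transcript disrupted

    relationship = (
        Relationship.PARTIAL_OVERLAP if partial else Relationship.VARIANT_WITHIN_ELEMENT
    )

    if coding_hit:
        frame = (
            _deletion_frame(region, tx, splice_width)
            if v.sv_type is SvType.DEL and tx.is_coding
            else FrameEffect.NA
        )
        return OverlapContext(
            relationship, Element.CODING_OR_SPLICE, frame,
            len_sv=len(region), extends_beyond_terminus=beyond,
            covers_tss=covers_tss,
        )
    if covers_tss:
        return OverlapContext(
            relationship, Element.TSS, len_sv=len(region),
            extends_beyond_terminus=beyond, covers_tss=True,
        )
    utr = _pick_utr(region, tx)
    if utr is not None:
        elem, ov, total = utr
        return OverlapContext(
            relationship, elem, len_sv=ov, len_utr=total,
            extends_beyond_terminus=beyond,
        )
    if overlaps(region, promoter.region):
        within = promoter.region.contains(region) and not overlaps(region, tx.region)
        return OverlapContext(
            Relationship.VARIANT_WITHIN_ELEMENT if within else relationship,
            Element.PROMOTER, len_sv=len(region),
            extends_beyond_terminus=beyond,
        )
    if _any_overlap(region, tx.introns()) > 0:
        return OverlapContext(
            relationship, Element.INTRON, len_sv=len(region),
            extends_beyond_terminus=beyond,
        )
    return _NEUTRAL


def _classify_insertion(
    v: HarmonizedVariant, tx: Transcript, promoter: PromoterRegion, splice_width: int
) -> OverlapContext:
    point = v.region.start
    rel = Relationship.VARIANT_WITHIN_ELEMENT
    if _point_in_any(point, tx.splice_regions(splice_width)):
        # insertion on a splice boundary: frameshift-equivalent coding hit
        return OverlapContext(
            rel, Element.CODING_OR_SPLICE, FrameEffect.FRAMESHIFT,
            len_ins=v.ins_length,
        )
    if _point_in_any(point, tx.coding_regions()) or (
        not tx.is_coding and _point_in_any(point, list(tx.exons))
    ):
        frame = (
            FrameEffect.IN_FRAME if v.ins_length % 3 == 0 else FrameEffect.FRAMESHIFT
        )
        return OverlapContext(rel, Element.CODING_OR_SPLICE, frame,
                              len_ins=v.ins_length)
    utr = _pick_utr(GenomicRegion(v.region.contig, point, point + 1), tx)
    if utr is not None:
        elem, _ov, total = utr
        return OverlapContext(rel, elem, len_ins=v.ins_length, len_utr=total)
    if promoter.region.contains_point(point):
        return OverlapContext(rel, Element.PROMOTER, len_ins=v.ins_length)
    if _point_in_any(point, tx.introns()):
        return OverlapContext(rel, Element.INTRON, len_ins=v.ins_length)
    return _NEUTRAL


# ---------------------------------------------------------------------------
# Class-specific δ rules


def _utr_deletion_score(ctx: OverlapContext) -> float:
    if ctx.len_utr == 0:
        return 0.0
    return min(2.0 * ctx.len_sv / ctx.len_utr, 1.0)


def delta_deletion(ctx: OverlapContext) -> float:
    if ctx.element is Element.NONE:
        return 0.0
    if ctx.relationship is Relationship.VARIANT_CONTAINS_TRANSCRIPT:
        return 1.0
    if ctx.element is Element.CODING_OR_SPLICE:
        return DELTA_INFRAME_EXON_DEL if ctx.frame_effect is FrameEffect.IN_FRAME else 1.0
    if ctx.element is Element.TSS:
        return 1.0  # TSS loss is as deleterious as a coding hit
    if ctx.element in (Element.UTR5, Element.UTR3):
        return _utr_deletion_score(ctx)
    if ctx.element is Element.PROMOTER:
        return DELTA_PROMOTER
    return 0.0  # intron


def delta_duplication(ctx: OverlapContext, copy_number_gain: int = 1) -> float:
    if ctx.element is Element.NONE:
        return 0.0
    if ctx.relationship is Relationship.VARIANT_CONTAINS_TRANSCRIPT:
        return float(copy_number_gain)
    if ctx.extends_beyond_terminus:
        # tandem copy appended outside the transcript: primary linear
        # transcript sequence unchanged
        return 0.0
    if ctx.element in (Element.CODING_OR_SPLICE, Element.TSS):
        return 1.0
    if ctx.element in (Element.UTR5, Element.UTR3):
        return _utr_deletion_score(ctx)
    if ctx.element is Element.PROMOTER:
        return DELTA_PROMOTER
    return 0.0


def delta_inversion(ctx: OverlapContext) -> float:
    if ctx.element is Element.NONE:
        return 0.0
    if ctx.relationship is Relationship.VARIANT_CONTAINS_TRANSCRIPT:
        return 0.0  # the transcript sequence itself is unchanged
    if ctx.relationship is Relationship.PARTIAL_OVERLAP and ctx.element in (
        Element.CODING_OR_SPLICE, Element.TSS, Element.UTR5, Element.UTR3,
        Element.INTRON,
    ):
        return 1.0  # a breakend falls inside the transcript
    if ctx.element in (Element.CODING_OR_SPLICE, Element.TSS):
        return 1.0
    if ctx.element in (Element.UTR5, Element.UTR3):
        return _utr_deletion_score(ctx)
    if ctx.element is Element.PROMOTER:
        return DELTA_PROMOTER
    return 0.0  # wholly intronic


def delta_insertion(ctx: OverlapContext) -> float:
    if ctx.element is Element.CODING_OR_SPLICE:
        return (
            DELTA_INFRAME_INS
            if ctx.frame_effect is FrameEffect.IN_FRAME
            else DELTA_FRAMESHIFT_INS
        )
    if ctx.element in (Element.UTR5, Element.UTR3):
        if ctx.len_utr == 0:
            return 0.0
        return min(ctx.len_ins / ctx.len_utr, 1.0)
    if ctx.element is Element.PROMOTER:
        return DELTA_PROMOTER
    return 0.0


def delta_breakend(
    adj: Adjacency,
    tx: Transcript,
    promoter: Optional[PromoterRegion] = None,
) -> tuple[float, OverlapContext]:
    """Score an adjacency against one transcript; both breakends count.

    Any breakend inside the transcript (coding, UTR, or intron) scores 1;
    a breakend in the promoter scores 0.4.
    """
    if promoter is None:
        promoter = promoter_of(tx)
    best = (0.0, _NEUTRAL)
    for be in (adj.left, adj.right):
        if be.contig.name != tx.region.contig.name:
            continue
        if tx.region.contains_point(be.position):
            ctx = OverlapContext(
                Relationship.PARTIAL_OVERLAP, Element.CODING_OR_SPLICE
            )
            return 1.0, ctx
        if promoter.region.contains_point(be.position):
            ctx = OverlapContext(
                Relationship.VARIANT_WITHIN_ELEMENT, Element.PROMOTER
            )
            best = max(best, (DELTA_PROMOTER, ctx), key=lambda t: t[0])
    return best


def gene_delta(
    v: HarmonizedVariant,
    gene: GeneModel,
    promoter_length: int = 2000,
    splice_width: int = DEFAULT_SPLICE_WIDTH,
) -> DeltaScore:
    """δ(g): score every transcript of the gene and keep the maximum."""
    if not isinstance(v.sv_type, SvType):
        raise ValueError(f"unknown SV type {v.sv_type!r}")
    score = DeltaScore(gene.gene_id, 0.0)
    for tx in gene.transcripts:
        prom = promoter_of(tx, promoter_length)
        if v.sv_type is SvType.BND:
            assert v.adjacency is not None
            delta, ctx = delta_breakend(v.adjacency, tx, prom)
        else:
            ctx = classify_overlap(v, tx, prom, splice_width)
            if v.sv_type is SvType.DEL:
                delta = delta_deletion(ctx)
            elif v.sv_type in (SvType.DUP, SvType.CNV):
                delta = delta_duplication(ctx, v.copy_number_gain)
            elif v.sv_type is SvType.INV:
                delta = delta_inversion(ctx)
            elif v.sv_type is SvType.INS:
                delta = delta_insertion(ctx)
            else:  # pragma: no cover
                raise ValueError(f"unknown SV type {v.sv_type!r}")
        score.per_transcript[tx.tx_id] = (delta, ctx)
        score.delta = max(score.delta, delta)
    return score
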
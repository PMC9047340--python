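"""Remove common and low-support SV calls before prioritization.

A call is dropped when some panel entry of a matching SV class has
population allele frequency strictly above the frequency threshold
(default 1%) and strictly more than the reciprocal-overlap threshold
(default 80%) reciprocal overlap with it.  Breakend records are never
frequency-filtered (reciprocal overlap is undefined for adjacencies),
and calls with unknown read depth are never depth-filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annotations import CommonSV
from .genome import HarmonizedVariant, SvType, reciprocal_overlap

logger = logging.getLogger(__name__)

DEFAULT_FREQ_THRESHOLD = 0.01
DEFAULT_OVERLAP_THRESHOLD = 0.80
DEFAULT_MIN_ALT_READS = 3
DEFAULT_INS_PADDING = 100

# Reciprocal overlap across SV classes is biologically meaningless;
# duplications are matched against CNV gains and vice versa.
_TYPE_CLASSES = {
    SvType.DEL: frozenset({SvType.DEL}),
    SvType.DUP: frozenset({SvType.DUP, SvType.CNV}),
    SvType.CNV: frozenset({SvType.DUP, SvType.CNV}),
    SvType.INV: frozenset({SvType.INV}),
    SvType.INS: frozenset({SvType.INS}),
}


@dataclass
class FilterResult:
    kept: list[HarmonizedVariant] = field(default_factory=list)
    removed: list[tuple[HarmonizedVariant, str]] = field(default_factory=list)


def insertion_match(
    v: HarmonizedVariant,
    c: CommonSV,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    padding: int = DEFAULT_INS_PADDING,
) -> bool:
    """Positional/length match between two insertions.

    Interval reciprocal overlap degenerates for zero-length anchors, so
    two insertions match when their anchor points lie within ``padding``
    bases and the length ratio min/max exceeds ``overlap_threshold``.
    """
    if v.sv_type is not SvType.INS or c.sv_type is not SvType.INS:
        return False
    if v.region.contig.name != c.region.contig.name:
        return False
    if abs(v.region.start - c.region.start) > padding:
        return False
    l1, l2 = v.ins_length, c.ins_length
    if l1 <= 0 or l2 <= 0:
        return False
    return min(l1, l2) / max(l1, l2) > overlap_threshold


class _PanelIndex:
    def __init__(self, panels: list[list[CommonSV]]):
        self.trees: dict[tuple[str, SvType], IntervalTree] = {}
        for panel in panels:
            for entry in panel:
                key = (entry.region.contig.name, entry.sv_type)
                tree = self.trees.setdefault(key, IntervalTree())
                start = entry.region.start
                end = max(entry.region.end, start + 1)  # INS anchors need width
                tree.addi(start, end, entry)

    def candidates(self, v: HarmonizedVariant, padding: int) -> list[CommonSV]:
        assert v.region is not None
        out = []
        for sv_type in _TYPE_CLASSES.get(v.sv_type, ()):  # BND: no classes
            tree = self.trees.get((v.region.contig.name, sv_type))
            if tree is None:
                continue
            lo = v.region.start - (padding if v.sv_type is SvType.INS else 0)
            hi = v.region.end + (padding if v.sv_type is SvType.INS else 0)
            out.extend(iv.data for iv in tree.overlap(lo, max(hi, lo + 1)))
        return out


def frequency_filter(
    variants: list[HarmonizedVariant],
    panels: list[list[CommonSV]],
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    ins_padding: int = DEFAULT_INS_PADDING,
) -> FilterResult:
    """Drop calls matching a common panel SV; panels combine with OR semantics."""
    if not (0 < freq_threshold <= 1) or not (0 < overlap_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    index = _PanelIndex(panels)
    result = FilterResult()
    for v in variants:
        if v.sv_type is SvType.BND:
            result.kept.append(v)
            continue
        match = None
        for entry in index.candidates(v, ins_padding):
            if entry.allele_frequency <= freq_threshold:
                continue
            if v.sv_type is SvType.INS:
                hit = insertion_match(v, entry, overlap_threshold, ins_padding)
            else:
                hit = reciprocal_overlap(v.region, entry.region) > overlap_threshold
            if hit:
                match = entry
                break
        if match is None:
            result.kept.append(v)
        else:
            reason = (
                f"common SV {match.sv_type.value} "
                f"{match.region.contig.name}:{match.region.start}-{match.region.end} "
                f"AF={match.allele_frequency:.4g}"
            )
            logger.info("removed %s: %s", v.id, reason)
            result.removed.append((v, reason))
    return result


def depth_filter(
    variants: list[HarmonizedVariant],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> FilterResult:
    """Drop calls whose ALT support is known and below ``min_alt_reads``.

    Calls with unknown depth are retained.
    """
    if min_alt_reads < 0:
        raise ValueError("min_alt_reads must be >= 0")
    result = FilterResult()
    for v in variants:
        if v.alt_read_count is not None and v.alt_read_count < min_alt_reads:
            result.removed.append(
                (v, f"ALT support {v.alt_read_count} < {min_alt_reads}")
            )
        else:
            result.kept.append(v)
    return result
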
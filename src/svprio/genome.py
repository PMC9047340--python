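"""Notation-independent genomic primitives and the harmonized SV model.

All internal coordinates are 0-based half-open on the forward strand;
VCF I/O converts at the boundary.  A structural variant is represented
either as a :class:`GenomicRegion` (DEL, DUP, INS, INV, CNV) or as a
single :class:`Adjacency` between two breakends (BND).  Insertions use a
zero-length anchor region at the insertion point plus an explicit
inserted length.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Strand(str, enum.Enum):
    POS = "+"
    NEG = "-"

    def opposite(self) -> "Strand":
        return Strand.NEG if self is Strand.POS else Strand.POS


class SvType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    CNV = "CNV"
    BND = "BND"


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Contig:
    """A reference sequence with a fixed length in base pairs."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.name!r} must have positive length")


@dataclass(frozen=True)
class GenomicRegion:
    """A stranded interval on a contig, 0-based half-open.

    The strand is an annotation (transcripts are stranded); interval
    algebra (overlap, distance) ignores it and always operates on the
    forward-strand coordinates stored here.
    """

    contig: Contig
    start: int
    end: int
    strand: Strand = Strand.POS

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end <= self.contig.length):
            raise ValueError(
                f"invalid region [{self.start}, {self.end}) on "
                f"{self.contig.name} (length {self.contig.length})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "GenomicRegion") -> bool:
        return (
            self.contig.name == other.contig.name
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection_length(self, other: "GenomicRegion") -> int:
        if self.contig.name != other.contig.name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_one_based(self) -> tuple[int, int]:
        """Return (start, end) as a 1-based fully-closed interval."""
        return self.start + 1, self.end

    @classmethod
    def from_one_based(
        cls, contig: Contig, start: int, end: int, strand: Strand = Strand.POS
    ) -> "GenomicRegion":
        return cls(contig, start - 1, end, strand)

    def with_strand(self, strand: Strand) -> "GenomicRegion":
        """Express the same physical interval in the coordinates of *strand*.

        Flipping the strand mirrors the coordinates through the contig:
        applying the flip twice is the identity.
        """
        if strand is self.strand:
            return self
        return GenomicRegion(
            self.contig,
            self.contig.length - self.end,
            self.contig.length - self.start,
            strand,
        )


def overlaps(a: GenomicRegion, b: GenomicRegion) -> bool:
    """True iff the intersection of ``a`` and ``b`` is non-empty."""
    return a.intersection_length(b) > 0


def distance(a: GenomicRegion, b: GenomicRegion) -> int:
    """Signed gap between two regions on one contig; 0 if they overlap or abut.

    Positive when ``b`` lies downstream (higher coordinates) of ``a``.
    """
    if a.contig.name != b.contig.name:
        raise ValueError("distance undefined across contigs")
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return -(a.start - b.end)
    return 0


def reciprocal_overlap(a: GenomicRegion, b: GenomicRegion) -> float:
    """min(ov/len(a), ov/len(b)); 0 for disjoint regions or empty input.

    Used to match called SVs against common-SV panel entries.  Zero-length
    regions (insertion anchors) are a degenerate case defined as 0 —
    insertions are matched by position and length instead.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0
    ov = a.intersection_length(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


@dataclass(frozen=True)
class Breakend:
    contig: Contig
    position: int  # 0-based
    strand: Strand

    def __post_init__(self) -> None:
        if not (0 <= self.position <= self.contig.length):
            raise ValueError(
                f"breakend position {self.position} outside {self.contig.name}"
            )

    def point_region(self) -> GenomicRegion:
        """A 1-bp region at the breakend, clipped at the contig end."""
        start = min(self.position, self.contig.length - 1)
        return GenomicRegion(self.contig, start, start + 1)


@dataclass(frozen=True)
class Adjacency:
    """A novel junction between two breakends (one VCF BND record).

    Each adjacency is analyzed individually; records are never grouped
    by their EVENT tag.
    """

    left: Breakend
    right: Breakend
    inserted_sequence: str = ""


@dataclass
class HarmonizedVariant:
    """One structural variant in a notation-independent form."""

    id: str
    sv_type: SvType
    region: Optional[GenomicRegion] = None
    ins_length: int = 0
    copy_number_gain: int = 1
    adjacency: Optional[Adjacency] = None
    alt_read_count: Optional[int] = None  # None = unknown; kept by the depth filter
    genotype: Genotype = Genotype.UNKNOWN
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sv_type is SvType.BND:
            if self.adjacency is None or self.region is not None:
                raise ValueError("BND variants carry an adjacency, not a region")
        else:
            if self.region is None or self.adjacency is not None:
                raise ValueError(f"{self.sv_type.value} variants carry a region")
            if self.sv_type in (SvType.DEL, SvType.INV) and len(self.region) < 1:
                raise ValueError(f"{self.sv_type.value} region must be >= 1 bp")
            if self.sv_type is SvType.INS and self.ins_length < 1:
                raise ValueError("insertion length must be >= 1 bp")
        if self.copy_number_gain < 1:
            raise ValueError("copy_number_gain must be >= 1")
        if self.alt_read_count is not None and self.alt_read_count < 0:
            raise ValueError("alt_read_count must be >= 0")

    @property
    def contig_names(self) -> tuple[str, ...]:
        if self.adjacency is not None:
            return (
                self.adjacency.left.contig.name,
                self.adjacency.right.contig.name,
            )
        assert self.region is not None
        return (self.region.contig.name,)

    def sv_length(self) -> int:
        """len_SV for region variants; inserted length for insertions."""
        if self.sv_type is SvType.INS:
            return self.ins_length
        if self.region is not None:
            return len(self.region)
        return 0
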
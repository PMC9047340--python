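"""Transcript models, promoters, common-SV panels, and interval indexes.

Transcripts can be loaded from GFF3 (``gene``/``mRNA``/``transcript``/
``exon``/``CDS`` features) or from a compact JSON dialect defined by this
package so that tests and examples need no external annotation download:

.. code-block:: json

    {
      "contigs": [{"name": "chr1", "length": 1000000}],
      "genes": [
        {"gene_id": "G1", "symbol": "GENE1", "transcripts": [
          {"tx_id": "G1.t1", "contig": "chr1", "strand": "+",
           "exons": [[1000, 1200], [1500, 1800]], "cds": [1100, 1700]}
        ]}
      ]
    }

All JSON coordinates are 0-based half-open on the forward strand; ``cds``
is ``null`` for non-coding transcripts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .genome import (
    Adjacency,
    Contig,
    GenomicRegion,
    HarmonizedVariant,
    Strand,
    SvType,
    overlaps,
)

PROMOTER_LENGTH = 2000  # bases upstream of the TSS assumed to act as promoter


@dataclass(frozen=True)
class Transcript:
    """A stranded exon structure with optional CDS bounds.

    ``exons`` are stored in forward-genomic coordinates, ordered 5'→3' on
    the transcript strand.  ``cds_start``/``cds_end`` bound the coding
    span in forward-genomic coordinates; both are ``None`` for
    non-coding transcripts.
    """

    tx_id: str
    gene_id: str
    region: GenomicRegion
    exons: tuple[GenomicRegion, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        fwd = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(fwd, fwd[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.tx_id}: overlapping exons")
        for e in fwd:
            if not self.region.contains(e):
                raise ValueError(f"transcript {self.tx_id}: exon outside span")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.tx_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (
                self.region.start <= self.cds_start < self.cds_end <= self.region.end
            ):
                raise ValueError(f"transcript {self.tx_id}: CDS outside span")

    @property
    def strand(self) -> Strand:
        return self.region.strand

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tss(self) -> int:
        """First transcribed base (0-based forward coordinate)."""
        return self.region.start if self.strand is Strand.POS else self.region.end - 1

    def exons_forward(self) -> list[GenomicRegion]:
        return sorted(self.exons, key=lambda e: e.start)

    def introns(self) -> list[GenomicRegion]:
        fwd = self.exons_forward()
        return [
            GenomicRegion(self.region.contig, a.end, b.start, self.strand)
            for a, b in zip(fwd, fwd[1:])
            if b.start > a.end
        ]

    def coding_regions(self) -> list[GenomicRegion]:
        if not self.is_coding:
            return []
        out = []
        for e in self.exons_forward():
            s = max(e.start, self.cds_start)
            t = min(e.end, self.cds_end)
            if t > s:
                out.append(GenomicRegion(self.region.contig, s, t, self.strand))
        return out

    def _utr_regions(self, five_prime: bool) -> list[GenomicRegion]:
        if not self.is_coding:
            return []
        upstream = five_prime == (self.strand is Strand.POS)
        out = []
        for e in self.exons_forward():
            if upstream:
                s, t = e.start, min(e.end, self.cds_start)
            else:
                s, t = max(e.start, self.cds_end), e.end
            if t > s:
                out.append(GenomicRegion(self.region.contig, s, t, self.strand))
        return out

    def utr5_regions(self) -> list[GenomicRegion]:
        return self._utr_regions(five_prime=True)

    def utr3_regions(self) -> list[GenomicRegion]:
        return self._utr_regions(five_prime=False)

    def utr5_length(self) -> int:
        return sum(len(r) for r in self.utr5_regions())

    def utr3_length(self) -> int:
        return sum(len(r) for r in self.utr3_regions())

    def splice_regions(self, width: int = 2) -> list[GenomicRegion]:
        """The ``width`` intronic bases flanking each exon boundary."""
        out = []
        for intr in self.introns():
            out.append(
                GenomicRegion(
                    self.region.contig, intr.start, min(intr.start + width, intr.end)
                )
            )
            out.append(
                GenomicRegion(
                    self.region.contig, max(intr.end - width, intr.start), intr.end
                )
            )
        return out


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    tx_id: str
    region: GenomicRegion


def promoter_of(tx: Transcript, length: int = PROMOTER_LENGTH) -> PromoterRegion:
    """The ``length`` bases immediately upstream of the TSS, clipped at contig bounds."""
    contig = tx.region.contig
    if tx.strand is Strand.POS:
        start = max(0, tx.region.start - length)
        region = GenomicRegion(contig, start, tx.region.start, Strand.POS)
    else:
        end = min(contig.length, tx.region.end + length)
        region = GenomicRegion(contig, tx.region.end, end, Strand.NEG)
    return PromoterRegion(tx.gene_id, tx.tx_id, region)


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    transcripts: list[Transcript]
    disease_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        contigs = {t.region.contig.name for t in self.transcripts}
        if len(contigs) > 1:
            raise ValueError(f"gene {self.gene_id} spans multiple contigs")

    @property
    def contig(self) -> Contig:
        return self.transcripts[0].region.contig

    def span(self) -> GenomicRegion:
        start = min(t.region.start for t in self.transcripts)
        end = max(t.region.end for t in self.transcripts)
        return GenomicRegion(self.contig, start, end)


@dataclass(frozen=True)
class CommonSV:
    """A population SV with its allele frequency, from a common-SV panel."""

    sv_type: SvType
    region: GenomicRegion
    allele_frequency: float
    ins_length: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError("allele frequency must be in [0, 1]")


# ---------------------------------------------------------------------------
# Loading


def _parse_json_obj(obj: dict) -> list[GeneModel]:
    contigs = {c["name"]: Contig(c["name"], int(c["length"])) for c in obj["contigs"]}
    genes = []
    for g in obj["genes"]:
        txs = []
        for t in g["transcripts"]:
            contig = contigs[t["contig"]]
            strand = Strand(t["strand"])
            exons = tuple(
                GenomicRegion(contig, int(s), int(e), strand) for s, e in t["exons"]
            )
            start = min(e.start for e in exons)
            end = max(e.end for e in exons)
            cds = t.get("cds")
            txs.append(
                Transcript(
                    tx_id=t["tx_id"],
                    gene_id=g["gene_id"],
                    region=GenomicRegion(contig, start, end, strand),
                    exons=exons,
                    cds_start=None if cds is None else int(cds[0]),
                    cds_end=None if cds is None else int(cds[1]),
                )
            )
        genes.append(GeneModel(g["gene_id"], g.get("symbol", g["gene_id"]), txs))
    return genes


def _parse_gff3(path: Path) -> list[GeneModel]:
    contigs: dict[str, Contig] = {}
    tx_meta: dict[str, dict] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    gene_symbol: dict[str, str] = {}

    def attrs(s: str) -> dict[str, str]:
        out = {}
        for part in s.strip().split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k] = v
        return out

    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, _start, end = line.split()[:4]
                contigs[name] = Contig(name, int(end))
                continue
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attr = (
                line.rstrip("\n").split("\t")
            )
            a = attrs(attr)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                gene_symbol[a["ID"]] = a.get("Name", a["ID"])
            elif ftype in ("mRNA", "transcript"):
                tx_meta[a["ID"]] = {
                    "gene": a.get("Parent", a["ID"]),
                    "contig": seqid,
                    "strand": strand,
                }
            elif ftype == "exon":
                tx_exons.setdefault(a["Parent"], []).append((start0, end0))
            elif ftype == "CDS":
                tx_cds.setdefault(a["Parent"], []).append((start0, end0))

    genes: dict[str, list[Transcript]] = {}
    for tx_id, meta in tx_meta.items():
        name = meta["contig"]
        if name not in contigs:
            # no ##sequence-region pragma: use a generous bound
            max_end = max(e for _, e in tx_exons.get(tx_id, [(0, 1)]))
            contigs[name] = Contig(name, max(max_end + PROMOTER_LENGTH, 1))
        contig = contigs[name]
        strand = Strand(meta["strand"])
        exon_pairs = sorted(tx_exons.get(tx_id, []))
        exons = tuple(GenomicRegion(contig, s, e, strand) for s, e in exon_pairs)
        region = GenomicRegion(contig, exons[0].start, exons[-1].end, strand)
        cds_pairs = tx_cds.get(tx_id)
        cds_start = min(s for s, _ in cds_pairs) if cds_pairs else None
        cds_end = max(e for _, e in cds_pairs) if cds_pairs else None
        genes.setdefault(meta["gene"], []).append(
            Transcript(tx_id, meta["gene"], region, exons, cds_start, cds_end)
        )
    return [
        GeneModel(gid, gene_symbol.get(gid, gid), txs) for gid, txs in genes.items()
    ]


def load_transcripts(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 or the JSON dialect (chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return _parse_json_obj(json.load(fh))
    return _parse_gff3(path)


def load_gene_diseases(path: str | Path, genes: Iterable[GeneModel]) -> None:
    """Attach disease ids to gene models from a two-column TSV (gene_id, disease_id)."""
    by_id = {g.gene_id: g for g in genes}
    by_symbol = {g.symbol: g for g in genes}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, disease_id = line.split("\t")[:2]
            gene = by_id.get(gene_id) or by_symbol.get(gene_id)
            if gene is not None and disease_id not in gene.disease_ids:
                gene.disease_ids.append(disease_id)


def load_common_sv_tsv(path: str | Path, contigs: dict[str, Contig]) -> list[CommonSV]:
    """Read a panel from TSV: contig, start, end, sv_type, AF[, ins_length].

    Coordinates are 0-based half-open (insertions: start == end anchor).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            contig_name, start, end, sv_type, af = parts[:5]
            ins_length = int(parts[5]) if len(parts) > 5 else 0
            contig = contigs[contig_name]
            out.append(
                CommonSV(
                    sv_type=SvType(sv_type),
                    region=GenomicRegion(contig, int(start), int(end)),
                    allele_frequency=float(af),
                    ins_length=ins_length,
                )
            )
    return out


def load_common_sv_vcf(path: str | Path, contigs: dict[str, Contig]) -> list[CommonSV]:
    """Read a panel from VCF; the allele frequency is taken from INFO/AF."""
    from .vcf_io import read_vcf  # local import to avoid a cycle

    result = read_vcf(path, assembly=contigs)
    out = []
    for v in result.variants:
        if v.sv_type is SvType.BND or v.region is None:
            continue
        af = v.info.get("AF")
        if af is None:
            continue
        if isinstance(af, (tuple, list)):
            af = af[0]
        out.append(
            CommonSV(
                sv_type=v.sv_type,
                region=v.region,
                allele_frequency=float(af),
                ins_length=v.ins_length,
            )
        )
    return out


def load_bed_track(path: str | Path, contigs: dict[str, Contig]) -> list[GenomicRegion]:
    """Optional annotation track (enhancers, repeats, dosage regions).

    Carried through to output annotations only; never enters the score.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig = contigs[parts[0]]
            out.append(GenomicRegion(contig, int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# Indexing and gene lookup


class GeneIndex:
    """Interval index over gene extents (transcripts plus promoters)."""

    def __init__(self, genes: Sequence[GeneModel], promoter_length: int = PROMOTER_LENGTH):
        self.genes = list(genes)
        self.promoter_length = promoter_length
        self.promoters: dict[str, list[PromoterRegion]] = {
            g.gene_id: [promoter_of(t, promoter_length) for t in g.transcripts]
            for g in self.genes
        }
        self._trees: dict[str, IntervalTree] = {}
        self._sorted: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in self.genes:
            span = g.span()
            lo = min([span.start] + [p.region.start for p in self.promoters[g.gene_id]])
            hi = max([span.end] + [p.region.end for p in self.promoters[g.gene_id]])
            tree = self._trees.setdefault(g.contig.name, IntervalTree())
            tree.addi(lo, hi, g)
            self._sorted.setdefault(g.contig.name, []).append((span.start, span.end, g))
        for lst in self._sorted.values():
            lst.sort(key=lambda t: (t[0], t[1], t[2].gene_id))

    def _hits(self, region: GenomicRegion) -> list[GeneModel]:
        tree = self._trees.get(region.contig.name)
        if tree is None:
            return []
        found = []
        query_end = region.end if region.end > region.start else region.start + 1
        for iv in tree.overlap(region.start, query_end):
            gene: GeneModel = iv.data
            for tx in gene.transcripts:
                if overlaps(region, tx.region) or (
                    len(region) == 0 and tx.region.contains_point(region.start)
                ):
                    found.append(gene)
                    break
            else:
                for p in self.promoters[gene.gene_id]:
                    if overlaps(region, p.region) or (
                        len(region) == 0 and p.region.contains_point(region.start)
                    ):
                        found.append(gene)
                        break
        return found

    def _nearest(self, contig_name: str, pos: int) -> list[GeneModel]:
        lst = self._sorted.get(contig_name, [])
        if not lst:
            return []
        upstream = None  # highest end <= pos
        downstream = None  # lowest start >= pos
        for start, end, g in lst:
            if end <= pos and (upstream is None or end > upstream[0]):
                upstream = (end, g)
            if start >= pos and downstream is None:
                downstream = (start, g)
        out = []
        if upstream is not None:
            out.append(upstream[1])
        if downstream is not None and (not out or downstream[1] is not out[0]):
            out.append(downstream[1])
        return out

    def genes_for_variant(self, v: HarmonizedVariant) -> list[GeneModel]:
        """Genes whose transcript or promoter the variant touches.

        For an intergenic variant, the nearest upstream and downstream
        genes are returned instead (either may be absent near contig
        ends).  BND variants are looked up at both breakends.
        """
        if v.sv_type is SvType.BND:
            assert v.adjacency is not None
            found: dict[str, GeneModel] = {}
            for be in (v.adjacency.left, v.adjacency.right):
                for g in self._hits(be.point_region()):
                    found[g.gene_id] = g
            if found:
                return sorted(found.values(), key=lambda g: g.gene_id)
            out: dict[str, GeneModel] = {}
            for be in (v.adjacency.left, v.adjacency.right):
                for g in self._nearest(be.contig.name, be.position):
                    out[g.gene_id] = g
            return sorted(out.values(), key=lambda g: g.gene_id)
        assert v.region is not None
        hits = {g.gene_id: g for g in self._hits(v.region)}
        if hits:
            return sorted(hits.values(), key=lambda g: g.gene_id)
        midpoint = (v.region.start + v.region.end) // 2
        return self._nearest(v.region.contig.name, midpoint)
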
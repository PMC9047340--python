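"""Read SV calls from VCF (sequence, symbolic, and breakend notation) and
write ranked results.

Every well-formed record maps to exactly one :class:`HarmonizedVariant`
or one logged skip; the counts reconcile.  Only the first ALT allele of a
multi-allelic record is processed.  Coordinates in emitted files are
1-based per VCF convention; a symbolic record with POS/END is decoded as
the fully-closed interval [POS, END], i.e. the half-open interval
[POS-1, END) internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from .genome import (
    Adjacency,
    Breakend,
    Contig,
    Genotype,
    GenomicRegion,
    HarmonizedVariant,
    Strand,
    SvType,
)

logger = logging.getLogger(__name__)

_BND_RE = re.compile(
    r"^(?P<head>[A-Za-z*.]*)"
    r"(?P<b1>[\[\]])(?P<contig>[^\[\]:]+):(?P<pos>\d+)(?P<b2>[\[\]])"
    r"(?P<tail>[A-Za-z*.]*)$"
)

SYMBOLIC_TYPES = {"DEL": SvType.DEL, "DUP": SvType.DUP, "INS": SvType.INS,
                  "INV": SvType.INV, "CNV": SvType.CNV}

DIALECTS = ("pbsv", "sniffles", "svim", "auto")


@dataclass
class ReadResult:
    """Variants plus the reconciliation bookkeeping of a VCF read."""

    variants: list[HarmonizedVariant] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (record id, reason)

    @property
    def n_records(self) -> int:
        return len(self.variants) + len(self.skipped)


def _contig_map(header: pysam.VariantHeader,
                assembly: Optional[dict] = None) -> dict[str, Contig]:
    contigs: dict[str, Contig] = {}
    if assembly:
        for name, c in assembly.items():
            contigs[name] = c if isinstance(c, Contig) else Contig(name, int(c))
    for name, rec in header.contigs.items():
        if name not in contigs and rec.length:
            contigs[name] = Contig(name, rec.length)
    return contigs


def _info_get(rec: pysam.VariantRecord, key: str):
    """INFO lookup tolerant of keys missing from the header (pysam raises)."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _sample_get(rec: pysam.VariantRecord, key: str):
    if not len(rec.samples):
        return None
    try:
        return rec.samples[0].get(key)
    except (KeyError, ValueError):
        return None


def extract_alt_depth(rec: pysam.VariantRecord, dialect: str = "auto") -> Optional[int]:
    """ALT-supporting read count under a caller dialect; ``None`` if absent.

    pbsv reports FORMAT AD (ref,alt); sniffles FORMAT DV (INFO RE as a
    fallback); SVIM INFO SUPPORT (FORMAT AD as a fallback).  ``auto``
    probes pbsv, sniffles, then svim.  Absence is a legal state — such
    variants stay in the analysis.
    """

    def from_ad() -> Optional[int]:
        ad = _sample_get(rec, "AD")
        if ad is not None and len(ad) >= 2 and ad[1] is not None:
            return int(ad[1])
        return None

    def from_dv() -> Optional[int]:
        dv = _sample_get(rec, "DV")
        if dv is not None:
            return int(dv[0] if isinstance(dv, tuple) else dv)
        re_ = _info_get(rec, "RE")
        if re_ is not None:
            return int(re_[0] if isinstance(re_, tuple) else re_)
        return None

    def from_support() -> Optional[int]:
        sup = _info_get(rec, "SUPPORT")
        if sup is not None:
            return int(sup[0] if isinstance(sup, tuple) else sup)
        return from_ad()

    if dialect == "pbsv":
        return from_ad()
    if dialect == "sniffles":
        return from_dv()
    if dialect == "svim":
        return from_support()
    if dialect == "auto":
        for probe in (from_ad, from_dv, from_support):
            value = probe()
            if value is not None:
                return value
        return None
    raise ValueError(f"unknown caller dialect {dialect!r}")


def _genotype(rec: pysam.VariantRecord) -> Genotype:
    gt = _sample_get(rec, "GT")
    if gt is None or all(a is None for a in gt):
        return Genotype.UNKNOWN
    alleles = [a for a in gt if a is not None]
    if len(alleles) == 1:
        return Genotype.HEMI if alleles[0] > 0 else Genotype.UNKNOWN
    if all(a > 0 for a in alleles):
        return Genotype.HOM
    if any(a > 0 for a in alleles):
        return Genotype.HET
    return Genotype.UNKNOWN


def _info_subset(rec: pysam.VariantRecord) -> dict:
    out = {}
    for key in ("AF", "SVTYPE", "EVENT"):
        if key in rec.info:
            out[key] = rec.info[key]
    return out


def _svlen(rec: pysam.VariantRecord) -> Optional[int]:
    svlen = _info_get(rec, "SVLEN")
    if svlen is None:
        return None
    if isinstance(svlen, tuple):
        svlen = svlen[0]
    return abs(int(svlen))


def _copy_number_gain(rec: pysam.VariantRecord) -> int:
    cn = _info_get(rec, "CN")
    if cn is None:
        cn = _sample_get(rec, "CN")
    if cn is None:
        return 1
    if isinstance(cn, tuple):
        cn = cn[0]
    return max(int(cn) - 2, 1)


def _decode_sequence(rec, contig, alt, rid) -> HarmonizedVariant:
    ref = rec.ref
    pos0 = rec.pos - 1
    if len(ref) > len(alt):
        start = pos0 + len(alt)
        end = start + (len(ref) - len(alt))
        region = GenomicRegion(contig, start, end)
        return HarmonizedVariant(rid, SvType.DEL, region=region)
    if len(alt) > len(ref):
        point = pos0 + len(ref)
        region = GenomicRegion(contig, point, point)
        return HarmonizedVariant(
            rid, SvType.INS, region=region, ins_length=len(alt) - len(ref)
        )
    raise ValueError("REF/ALT of equal length is not a structural variant")


def _decode_symbolic(rec, contig, alt, rid) -> HarmonizedVariant:
    token = alt.strip("<>").split(":")[0].upper()
    if token not in SYMBOLIC_TYPES:
        raise ValueError(f"unsupported symbolic allele {alt}")
    sv_type = SYMBOLIC_TYPES[token]
    svlen = _svlen(rec)
    if sv_type is SvType.INS:
        if svlen is None:
            raise ValueError("symbolic <INS> without SVLEN")
        point = rec.pos  # 0-based insertion point right of the anchor base
        region = GenomicRegion(contig, point, point)
        return HarmonizedVariant(rid, SvType.INS, region=region, ins_length=svlen)
    # SVLEN, when present, fixes the region length (htslib folds INFO/END
    # into rec.stop and prefers SVLEN, so END is not separately visible);
    # an END-only record spans [POS, END] 1-based inclusive.
    if svlen is not None:
        end0 = rec.pos - 1 + svlen
    elif rec.stop != rec.start + len(rec.ref or "N"):
        end0 = rec.stop
    else:
        raise ValueError("symbolic allele without END or SVLEN")
    region = GenomicRegion(contig, rec.pos - 1, int(end0))
    gain = _copy_number_gain(rec) if sv_type in (SvType.DUP, SvType.CNV) else 1
    return HarmonizedVariant(rid, sv_type, region=region, copy_number_gain=gain)


def _decode_breakend(rec, contig, alt, rid, contigs) -> HarmonizedVariant:
    m = _BND_RE.match(alt)
    if not m or m.group("b1") != m.group("b2"):
        raise ValueError(f"malformed breakend ALT {alt!r}")
    mate_name = m.group("contig")
    if mate_name not in contigs:
        raise ValueError(f"breakend mate contig {mate_name!r} unknown")
    head, tail = m.group("head"), m.group("tail")
    # t before the bracket: the sequence up to POS is retained (+); after: (-)
    left_strand = Strand.POS if head else Strand.NEG
    # '[' joins to the mate sequence extending rightwards (+); ']' leftwards (-)
    right_strand = Strand.POS if m.group("b1") == "[" else Strand.NEG
    inserted = head[len(rec.ref):] if head else tail[: max(len(tail) - len(rec.ref), 0)]
    left = Breakend(contig, rec.pos - 1, left_strand)
    right = Breakend(contigs[mate_name], int(m.group("pos")) - 1, right_strand)
    return HarmonizedVariant(
        rid, SvType.BND, adjacency=Adjacency(left, right, inserted)
    )


def read_vcf(
    path: str | Path,
    assembly: Optional[dict] = None,
    dialect: str = "auto",
    pass_only: bool = False,
) -> ReadResult:
    """Decode a VCF of SV calls into harmonized variants.

    Parameters
    ----------
    path : VCF file (plain text or bgzipped).
    assembly : optional ``{name: Contig | length}`` map supplementing the
        header's ``##contig`` lines.
    dialect : caller dialect for ALT read depth (``pbsv``, ``sniffles``,
        ``svim`` or ``auto``).
    pass_only : when True, records whose FILTER is not PASS/. are skipped.
    """
    result = ReadResult()
    with pysam.VariantFile(str(path)) as vcf:
        contigs = _contig_map(vcf.header, assembly)
        for i, rec in enumerate(vcf):
            rid = rec.id or f"{rec.chrom}:{rec.pos}#{i}"
            try:
                if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                    raise ValueError("non-PASS record in PASS-only mode")
                if rec.chrom not in contigs:
                    raise ValueError(f"contig {rec.chrom!r} not in assembly")
                contig = contigs[rec.chrom]
                if not rec.alts:
                    raise ValueError("record has no ALT allele")
                if len(rec.alts) > 1:
                    logger.warning("record %s is multi-allelic; using first ALT", rid)
                alt = rec.alts[0]
                if alt.startswith("<"):
                    variant = _decode_symbolic(rec, contig, alt, rid)
                elif "[" in alt or "]" in alt:
                    variant = _decode_breakend(rec, contig, alt, rid, contigs)
                else:
                    variant = _decode_sequence(rec, contig, alt, rid)
                variant.alt_read_count = extract_alt_depth(rec, dialect)
                variant.genotype = _genotype(rec)
                variant.info = _info_subset(rec)
                result.variants.append(variant)
            except (ValueError, KeyError) as exc:
                logger.warning("skipping record %s: %s", rid, exc)
                result.skipped.append((rid, str(exc)))
    return result


# ---------------------------------------------------------------------------
# Writing


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
    '##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number">',
    '##INFO=<ID=PSV,Number=1,Type=Float,Description="Pathogenicity of SV score">',
    '##INFO=<ID=RANK,Number=1,Type=Integer,Description="Priority rank">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=CNV,Description="Copy number variant">',
]


def _variant_vcf_fields(v: HarmonizedVariant) -> tuple[str, int, str, str]:
    """(contig, POS 1-based, ALT, INFO core) for re-emitting a variant."""
    if v.sv_type is SvType.BND:
        adj = v.adjacency
        mate_pos = adj.right.position + 1
        bracket = "[" if adj.right.strand is Strand.POS else "]"
        mate = f"{bracket}{adj.right.contig.name}:{mate_pos}{bracket}"
        ins = adj.inserted_sequence
        alt = f"N{ins}{mate}" if adj.left.strand is Strand.POS else f"{mate}{ins}N"
        return adj.left.contig.name, adj.left.position + 1, alt, "SVTYPE=BND"
    region = v.region
    if v.sv_type is SvType.INS:
        info = f"SVTYPE=INS;SVLEN={v.ins_length}"
        return region.contig.name, region.start, "<INS>", info
    sign = "-" if v.sv_type is SvType.DEL else ""
    info = f"SVTYPE={v.sv_type.value};END={region.end};SVLEN={sign}{len(region)}"
    if v.sv_type in (SvType.DUP, SvType.CNV) and v.copy_number_gain > 1:
        info += f";CN={v.copy_number_gain + 2}"
    return region.contig.name, region.start + 1, "<" + v.sv_type.value + ">", info


TSV_COLUMNS = [
    "rank", "median_rank", "psv", "id", "type", "contig", "start", "end",
    "genes", "gene_scores", "diseases",
]


def write_results(prioritized, tsv_path, vcf_path, contigs=None) -> None:
    """Write ranked variants as a TSV table and an annotated VCF.

    The TSV carries one row per variant with the per-gene deleteriousness
    and phenotype-similarity breakdown; the VCF re-emits each call in
    symbolic/breakend notation with PSV and RANK INFO fields.  Start/end
    columns are 1-based inclusive.
    """
    rows = []
    for pv in prioritized:
        v = pv.variant
        if v.region is not None:
            contig = v.region.contig.name
            start1, end1 = v.region.to_one_based()
            if v.sv_type is SvType.INS:
                start1, end1 = v.region.start, v.region.start
        else:
            contig = v.adjacency.left.contig.name
            start1 = end1 = v.adjacency.left.position + 1
        genes = ",".join(c.gene_id for c in pv.contributions) or "."
        gene_scores = ";".join(
            f"{c.gene_id}:delta={c.delta:.4g}:phi={c.phi:.4g}"
            for c in pv.contributions
        ) or "."
        diseases = ",".join(
            sorted({c.disease_id for c in pv.contributions if c.disease_id})
        ) or "."
        rows.append(
            [pv.rank, pv.median_rank, f"{pv.psv:.6g}", v.id, v.sv_type.value,
             contig, start1, end1, genes, gene_scores, diseases]
        )

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    if contigs is None:
        seen: dict[str, Contig] = {}
        for pv in prioritized:
            v = pv.variant
            if v.region is not None:
                seen[v.region.contig.name] = v.region.contig
            else:
                for be in (v.adjacency.left, v.adjacency.right):
                    seen[be.contig.name] = be.contig
        contigs = seen

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(contigs.values(), key=lambda c: c.name):
            fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pv in prioritized:
            chrom, pos, alt, info = _variant_vcf_fields(pv.variant)
            info += f";PSV={pv.psv:.6g};RANK={pv.rank}"
            fh.write(
                f"{chrom}\t{pos}\t{pv.variant.id}\tN\t{alt}\t.\tPASS\t{info}\n"
            )
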
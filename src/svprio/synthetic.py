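"""Synthetic inputs: a toy annotation world, background SV call sets, and
a desk-scale spike-in benchmark harness.

The generator emits every format the pipeline consumes (VCF, the JSON
transcript dialect, OBO, TSVs), entirely from code, so that tests and
examples need no external downloads.  Background call sets are neutral
by construction — variants are placed deep inside introns, in intergenic
space clear of promoters, or duplicated from the common-SV panel — so a
deleterious, phenotype-matched spike-in should take rank 1.
"""

from __future__ import annotations

import math
import random
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .annotations import GeneModel, PROMOTER_LENGTH, Transcript
from .genome import Contig, GenomicRegion, Strand, SvType
from .pipeline import Config, run_prioritize

# gene layout relative to the gene start s (0-based, forward strand):
#   exon1 [s, s+300)        UTR5 [s, s+100), CDS from s+100
#   exon2 [s+5000, s+5144)  144 coding bases (an in-frame unit)
#   exon3 [s+9000, s+10000) CDS to s+9800, UTR3 [s+9800, s+10000)
GENE_SPAN = 10_000
EXON2_OFFSET = 5_000
EXON2_LENGTH = 144
CDS_OFFSET = 100
CDS_END_OFFSET = 9_800


@dataclass
class ToyWorld:
    contigs: dict[str, Contig]
    genes: list[GeneModel]
    ontology_terms: dict[str, list[str]]  # term -> parent ids ([] for root)
    root_term: str
    diseases: dict[str, list[str]]  # disease -> term ids
    gene_diseases: dict[str, str]  # gene_id -> disease id
    common_panel: list[tuple] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def disease_terms_for_gene(self, gene_id: str) -> list[str]:
        return self.diseases[self.gene_diseases[gene_id]]


def _make_gene(
    gene_id: str,
    contig: Contig,
    start: int,
    strand: Strand = Strand.POS,
    coding: bool = True,
    second_transcript: bool = False,
) -> GeneModel:
    exons = (
        GenomicRegion(contig, start, start + 300, strand),
        GenomicRegion(contig, start + EXON2_OFFSET,
                      start + EXON2_OFFSET + EXON2_LENGTH, strand),
        GenomicRegion(contig, start + 9_000, start + GENE_SPAN, strand),
    )
    region = GenomicRegion(contig, start, start + GENE_SPAN, strand)
    txs = [
        Transcript(
            f"{gene_id}.t1", gene_id, region, exons,
            cds_start=start + CDS_OFFSET if coding else None,
            cds_end=start + CDS_END_OFFSET if coding else None,
        )
    ]
    if second_transcript:
        # exon2-skipping isoform: same span, middle exon absent
        txs.append(
            Transcript(
                f"{gene_id}.t2", gene_id, region, (exons[0], exons[2]),
                cds_start=start + CDS_OFFSET if coding else None,
                cds_end=start + CDS_END_OFFSET if coding else None,
            )
        )
    return GeneModel(gene_id, gene_id, txs)


def make_toy_annotation(seed: int = 0) -> ToyWorld:
    """A deterministic toy genome, ontology, and disease corpus.

    Twelve genes over three contigs (plus/minus strand, coding and
    non-coding, a two-isoform gene, an adjacent gene pair), a 36-term
    rooted DAG, eight disease models, and a gene–disease map.  The
    output is identical for a given seed.
    """
    del seed  # the toy world is fixed; the seed shapes backgrounds/cases
    chr1 = Contig("chr1", 2_000_000)
    chr2 = Contig("chr2", 1_000_000)
    chr3 = Contig("chr3", 500_000)
    contigs = {c.name: c for c in (chr1, chr2, chr3)}

    genes = [
        _make_gene("G01", chr1, 100_000),
        _make_gene("G02", chr1, 200_000, second_transcript=True),
        _make_gene("G03", chr1, 300_000, strand=Strand.NEG),
        _make_gene("G04", chr1, 400_000),
        _make_gene("G05", chr1, 500_000),
        _make_gene("G06", chr1, 600_000, strand=Strand.NEG),
        _make_gene("G07", chr1, 700_000),
        _make_gene("G08", chr2, 100_000),
        _make_gene("G09", chr2, 300_000),
        _make_gene("G10", chr2, 500_000, coding=False),
        # adjacent pair for multi-gene / intergenic lookups
        _make_gene("G11", chr3, 100_000),
        _make_gene("G12", chr3, 120_000),
    ]

    root = "HP:0000001"
    terms: dict[str, list[str]] = {root: []}
    branches = []
    counter = 2
    for _b in range(5):
        branch = f"HP:{counter:07d}"
        counter += 1
        terms[branch] = [root]
        mids = []
        for _m in range(2):
            mid = f"HP:{counter:07d}"
            counter += 1
            terms[mid] = [branch]
            leaves = []
            for _l in range(2):
                leaf = f"HP:{counter:07d}"
                counter += 1
                terms[leaf] = [mid]
                leaves.append(leaf)
            mids.append((mid, leaves))
        branches.append((branch, mids))

    diseases: dict[str, list[str]] = {}
    for i in range(8):
        branch, mids = branches[i % 5]
        mid, leaves = mids[i % 2]
        annot = list(leaves) + [mid]
        if i >= 5:  # later diseases borrow a leaf from the next branch
            other_branch, other_mids = branches[(i + 1) % 5]
            annot.append(other_mids[0][1][0])
        diseases[f"DIS:{i + 1:04d}"] = annot

    gene_diseases = {
        f"G{k + 1:02d}": f"DIS:{(k % 8) + 1:04d}" for k in range(9)
    }
    gene_diseases["G11"] = "DIS:0001"
    # G10 (non-coding) and G12 have no disease association

    world = ToyWorld(contigs, genes, terms, root, diseases, gene_diseases)
    for g in world.genes:
        d = world.gene_diseases.get(g.gene_id)
        if d:
            g.disease_ids.append(d)
    world.common_panel = _make_panel(world)
    return world


def _make_panel(world: ToyWorld) -> list[tuple]:
    """(contig, start, end, type, AF, ins_length) rows; intergenic placement."""
    rows = []
    spots = [(("chr1"), 150_000), ("chr1", 250_000), ("chr1", 350_000),
             ("chr1", 450_000), ("chr2", 150_000), ("chr2", 350_000),
             ("chr3", 200_000)]
    for i, (cname, pos) in enumerate(spots):
        sv_type = ("DEL", "DUP", "INV")[i % 3]
        rows.append((cname, pos, pos + 1_000 + 200 * i, sv_type, 0.05, 0))
    rows.append(("chr1", 155_000, 155_000, "INS", 0.08, 300))
    rows.append(("chr1", 165_000, 166_000, "DEL", 0.005, 0))  # rare: never filters
    return rows


def write_world(world: ToyWorld, out_dir: str | Path) -> dict[str, Path]:
    """Emit transcripts.json, ontology.obo, diseases.tsv, gene_disease.tsv,
    and common_panel.tsv; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": out / "transcripts.json",
        "obo": out / "ontology.obo",
        "disease_annotations": out / "diseases.tsv",
        "gene_disease": out / "gene_disease.tsv",
        "panel": out / "common_panel.tsv",
    }

    import json

    tx_obj = {
        "contigs": [
            {"name": c.name, "length": c.length} for c in world.contigs.values()
        ],
        "genes": [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "transcripts": [
                    {
                        "tx_id": t.tx_id,
                        "contig": t.region.contig.name,
                        "strand": t.strand.value,
                        "exons": [[e.start, e.end] for e in t.exons],
                        "cds": None if not t.is_coding
                        else [t.cds_start, t.cds_end],
                    }
                    for t in g.transcripts
                ],
            }
            for g in world.genes
        ],
    }
    paths["transcripts"].write_text(json.dumps(tx_obj, indent=1))

    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\nontology: toy-phenotype\n\n")
        for term, parents in world.ontology_terms.items():
            fh.write(f"[Term]\nid: {term}\nname: term {term}\n")
            for p in parents:
                fh.write(f"is_a: {p} ! term {p}\n")
            fh.write("\n")

    with open(paths["disease_annotations"], "w") as fh:
        for disease, ts in world.diseases.items():
            for t in ts:
                fh.write(f"{disease}\t{t}\n")

    with open(paths["gene_disease"], "w") as fh:
        for gene_id, disease in world.gene_diseases.items():
            fh.write(f"{gene_id}\t{disease}\n")

    with open(paths["panel"], "w") as fh:
        fh.write("#contig\tstart\tend\tsv_type\taf\tins_length\n")
        for row in world.common_panel:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return paths


# ---------------------------------------------------------------------------
# VCF emission

_VCF_META = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant read depth">
"""


def _vcf_header(contigs: dict[str, Contig], sample: str = "proband") -> str:
    lines = [_VCF_META]
    for c in contigs.values():
        lines.append(f"##contig=<ID={c.name},length={c.length}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
    )
    return "".join(lines)


def _fmt_record(chrom, pos1, vid, ref, alt, info, ref_depth, alt_depth,
                gt="0/1") -> str:
    fmt = f"{gt}:{ref_depth},{alt_depth}"
    return (
        f"{chrom}\t{pos1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:AD\t{fmt}\n"
    )


def symbolic_record(vid: str, sv_type: str, contig: str, start0: int, end0: int,
                    alt_depth: int = 8, ref_depth: int = 8, cn: Optional[int] = None,
                    gt: str = "0/1") -> str:
    """One symbolic-notation record line ([start0, end0) internal coords)."""
    if sv_type == "INS":
        raise ValueError("use insertion_record for insertions")
    sign = "-" if sv_type == "DEL" else ""
    info = f"SVTYPE={sv_type};END={end0};SVLEN={sign}{end0 - start0}"
    if cn is not None:
        info += f";CN={cn}"
    return _fmt_record(contig, start0 + 1, vid, "N", f"<{sv_type}>", info,
                       ref_depth, alt_depth, gt)


def insertion_record(vid: str, contig: str, point0: int, length: int,
                     alt_depth: int = 8, ref_depth: int = 8,
                     sequence: bool = False, rng: Optional[random.Random] = None,
                     gt: str = "0/1") -> str:
    if sequence:
        rng = rng or random.Random(point0)
        ins = "".join(rng.choice("ACGT") for _ in range(length))
        # sequence notation: POS anchors the base before the insertion point
        return _fmt_record(contig, point0, vid, "A", "A" + ins,
                           "SVTYPE=INS", ref_depth, alt_depth, gt)
    return _fmt_record(contig, point0, vid, "N", "<INS>",
                       f"SVTYPE=INS;SVLEN={length}", ref_depth, alt_depth, gt)


def deletion_sequence_record(vid: str, contig: str, start0: int, end0: int,
                             alt_depth: int = 8, ref_depth: int = 8,
                             rng: Optional[random.Random] = None,
                             gt: str = "0/1") -> str:
    rng = rng or random.Random(start0)
    deleted = "".join(rng.choice("ACGT") for _ in range(end0 - start0))
    return _fmt_record(contig, start0, vid, "A" + deleted, "A",
                       "SVTYPE=DEL", ref_depth, alt_depth, gt)


def breakend_record(vid: str, contig: str, pos0: int, mate_contig: str,
                    mate_pos0: int, alt_depth: int = 8, ref_depth: int = 8,
                    gt: str = "0/1") -> str:
    alt = f"N[{mate_contig}:{mate_pos0 + 1}["
    return _fmt_record(contig, pos0 + 1, vid, "N", alt, "SVTYPE=BND",
                       ref_depth, alt_depth, gt)


def _neutral_zones(world: ToyWorld) -> tuple[list, list]:
    """Intergenic windows (clear of promoters) and deep-intron windows."""
    margin = PROMOTER_LENGTH + 1_000
    intergenic = []
    for cname, contig in world.contigs.items():
        spans = sorted(
            (g.span().start, g.span().end)
            for g in world.genes
            if g.contig.name == cname
        )
        prev = 10_000
        for s, e in spans:
            if s - margin - prev > 20_000:
                intergenic.append((cname, prev, s - margin))
            prev = e + margin
        if contig.length - 10_000 - prev > 20_000:
            intergenic.append((cname, prev, contig.length - 10_000))
    introns = []
    for g in world.genes:
        for t in g.transcripts[:1]:
            for intr in t.introns():
                if len(intr) > 2_000:
                    introns.append(
                        (g.contig.name, intr.start + 500, intr.end - 500)
                    )
    return intergenic, introns


def make_background_vcf(
    n_variants: int,
    seed: int,
    world: Optional[ToyWorld] = None,
    path: Optional[str | Path] = None,
) -> str:
    """A neutral background call set mixing all five SV classes and all
    three VCF notations, with pbsv-style depth fields.

    Roughly 10% of region variants copy a common-panel entry (removed by
    the frequency filter) and 5% carry ALT support below three reads
    (removed by the depth filter).  At least one breakend record is
    present whenever ``n_variants`` >= 50.  Returns the VCF text; writes
    it to ``path`` when given.
    """
    world = world or make_toy_annotation(seed)
    rng = random.Random(seed)
    intergenic, introns = _neutral_zones(world)
    records: list[tuple[str, int, str]] = []  # (contig, pos for sorting, line)
    n_bnd = 0
    for i in range(n_variants):
        vid = f"bg{i:05d}"
        alt_depth = 2 if rng.random() < 0.05 else rng.randint(4, 20)
        ref_depth = rng.randint(4, 20)
        roll = rng.random()
        if roll < 0.10 and world.common_panel:
            cname, s, e, sv_type, _af, ins_len = rng.choice(
                world.common_panel[:-1]  # skip the rare entry
            )
            if sv_type == "INS":
                line = insertion_record(vid, cname, s, ins_len,
                                        alt_depth, ref_depth)
            else:
                line = symbolic_record(vid, sv_type, cname, s, e,
                                       alt_depth, ref_depth)
            records.append((cname, s, line))
            continue
        sv_type = rng.choices(
            ["DEL", "INS", "DUP", "INV", "CNV", "BND"],
            weights=[0.28, 0.28, 0.15, 0.15, 0.07, 0.07],
        )[0]
        # breakends score 1 anywhere inside a transcript (introns included),
        # so neutral BNDs must be intergenic at both ends
        zone_pool = intergenic if sv_type == "BND" else (
            introns if rng.random() < 0.5 else intergenic
        )
        cname, lo, hi = rng.choice(zone_pool)
        if sv_type == "BND":
            n_bnd += 1
            c2, lo2, hi2 = rng.choice(intergenic)
            pos, pos2 = rng.randint(lo, hi - 1), rng.randint(lo2, hi2 - 1)
            line = breakend_record(vid, cname, pos, c2, pos2,
                                   alt_depth, ref_depth)
            records.append((cname, pos, line))
            continue
        if sv_type == "INS":
            point = rng.randint(lo, hi - 1)
            length = rng.randint(50, 500)
            line = insertion_record(vid, cname, point, length, alt_depth,
                                    ref_depth, sequence=rng.random() < 0.3,
                                    rng=rng)
            records.append((cname, point, line))
            continue
        size = rng.randint(100, min(5_000, hi - lo - 1))
        start = rng.randint(lo, hi - size)
        end = start + size
        if sv_type == "DEL" and rng.random() < 0.3:
            line = deletion_sequence_record(vid, cname, start, end,
                                            alt_depth, ref_depth, rng=rng)
        else:
            cn = rng.choice([3, 4]) if sv_type == "CNV" else None
            line = symbolic_record(vid, sv_type, cname, start, end,
                                   alt_depth, ref_depth, cn=cn)
        records.append((cname, start, line))
    if n_variants >= 50 and n_bnd == 0 and records:
        cname, lo, hi = intergenic[0]
        c2, lo2, hi2 = intergenic[-1]
        records[-1] = (
            cname, lo,
            breakend_record(f"bg{n_variants - 1:05d}", cname, lo, c2, lo2),
        )
    records.sort(key=lambda r: (r[0], r[1]))
    text = _vcf_header(world.contigs) + "".join(line for _c, _p, line in records)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Spike-in cases and the benchmark harness

CASE_CLASSES = ("DEL", "DUP", "INS", "INV", "BND")


@dataclass
class SpikeInCase:
    case_id: str
    sv_class: str
    vcf_lines: list[str]
    causal_ids: list[str]
    query_terms: list[str]
    unambiguous: bool = True


def make_case(sv_class: str, world: ToyWorld, seed: int = 0) -> SpikeInCase:
    """A deleterious, phenotype-matched causal variant of the given class.

    The target gene rotates with the seed; allelic depth is 5:5 so the
    causal call always survives the depth filter.
    """
    rng = random.Random(seed)
    candidates = [g for g in world.genes
                  if g.disease_ids and g.transcripts[0].is_coding]
    gene = candidates[seed % len(candidates)]
    s = gene.span().start
    cname = gene.contig.name
    vid = f"causal_{sv_class}_{seed}"
    kw = dict(alt_depth=5, ref_depth=5)
    if sv_class == "DEL":
        # whole middle exon plus flanking intron: in-frame exon loss
        line = symbolic_record(vid, "DEL", cname, s + EXON2_OFFSET - 10,
                               s + EXON2_OFFSET + EXON2_LENGTH + 10, **kw)
    elif sv_class == "DUP":
        line = symbolic_record(vid, "DUP", cname, s - 100,
                               s + GENE_SPAN + 100, **kw)
    elif sv_class == "INS":
        point = s + 9_100 + rng.randint(0, 200)  # inside the coding third exon
        line = insertion_record(vid, cname, point, 35, **kw)
    elif sv_class == "INV":
        line = symbolic_record(vid, "INV", cname, s - 500, s + 200, **kw)
    elif sv_class == "BND":
        other = world.contigs["chr3"]
        line = breakend_record(vid, cname, s + 9_100, other.name, 400_000, **kw)
    else:
        raise ValueError(f"unknown case class {sv_class!r}")
    return SpikeInCase(
        case_id=vid,
        sv_class=sv_class,
        vcf_lines=[line],
        causal_ids=[vid],
        query_terms=list(world.disease_terms_for_gene(gene.gene_id)),
    )


FILTERED_OUT = math.inf  # sentinel rank for a causal variant lost to filtering


def run_spike_in_suite(
    workdir: str | Path,
    n_cases: int = 20,
    n_backgrounds: int = 3,
    background_size: int = 120,
    seed: int = 0,
    config: Config = Config(),
) -> list[tuple[SpikeInCase, float, list[float]]]:
    """Seeded spike-in recovery benchmark across all five SV classes.

    ``n_cases`` cases cycle through DEL, DUP, INS, INV, and BND, each
    spiked into ``n_backgrounds`` fresh neutral backgrounds; returns one
    (case, median rank, per-background ranks) triple per case.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    world = make_toy_annotation(seed)
    resources = write_world(world, workdir / "resources")
    backgrounds = []
    for i in range(n_backgrounds):
        p = workdir / f"background_{i}.vcf"
        make_background_vcf(background_size, seed * 1_000 + i, world, p)
        backgrounds.append(p)
    results = []
    for i in range(n_cases):
        sv_class = CASE_CLASSES[i % len(CASE_CLASSES)]
        case = make_case(sv_class, world, seed=seed + i)
        median, ranks = spike_in_and_rank(
            case, backgrounds, resources, workdir / "runs", config
        )
        results.append((case, median, ranks))
    return results


def spike_in_and_rank(
    case: SpikeInCase,
    background_vcfs: Sequence[str | Path],
    resources: dict[str, Path],
    workdir: str | Path,
    config: Config = Config(),
) -> tuple[float, list[float]]:
    """Insert the case's variants into each background, run the pipeline,
    and return (median, per-file) best causal rank.

    Ranks use the tie-aware middle-of-group convention.  A causal variant
    removed by filtering is reported with an infinite sentinel rank.
    """
    if not background_vcfs:
        raise ValueError("at least one background VCF is required")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ranks: list[float] = []
    for i, bg in enumerate(background_vcfs):
        merged = workdir / f"{case.case_id}_bg{i}.vcf"
        text = Path(bg).read_text()
        header, _, body = text.partition("#CHROM")
        body_lines = body.splitlines(keepends=True)
        merged.write_text(
            header + "#CHROM" + body_lines[0]
            + "".join(body_lines[1:] + case.vcf_lines)
        )
        ranked, _summary = run_prioritize(
            merged,
            resources["transcripts"],
            [resources["panel"]],
            resources["obo"],
            resources["disease_annotations"],
            resources["gene_disease"],
            case.query_terms,
            workdir / f"{case.case_id}_bg{i}_out",
            config,
        )
        by_id = {pv.variant.id: pv for pv in ranked}
        case_ranks = [
            by_id[cid].median_rank for cid in case.causal_ids if cid in by_id
        ]
        if not case_ranks:
            import logging

            logging.getLogger(__name__).warning(
                "causal variant(s) %s filtered out of %s",
                case.causal_ids, merged,
            )
            ranks.append(FILTERED_OUT)
        else:
            ranks.append(min(case_ranks))
    return statistics.median(ranks), ranks
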
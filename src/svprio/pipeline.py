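"""End-to-end prioritization: read → filter → score → rank → write.

The pipeline is fully deterministic: identical inputs produce
byte-identical TSV output.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import annotations as ann
from . import filtering, phenotype, vcf_io
from .deleteriousness import gene_delta
from .genome import Contig, SvType
from .prioritization import PrioritizedVariant, psv_score, rank_variants

logger = logging.getLogger(__name__)

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*:\S+$")


@dataclass
class Config:
    """Every CLI flag has a config-file counterpart; CLI overrides config."""

    frequency_threshold: float = filtering.DEFAULT_FREQ_THRESHOLD
    overlap_threshold: float = filtering.DEFAULT_OVERLAP_THRESHOLD
    min_read_support: int = filtering.DEFAULT_MIN_ALT_READS
    ins_padding: int = filtering.DEFAULT_INS_PADDING
    promoter_length: int = ann.PROMOTER_LENGTH
    splice_width: int = 2
    caller_dialect: str = "auto"
    pass_only: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_phenotype_terms(
    terms: Sequence[str] = (),
    phenopacket_path: Optional[str | Path] = None,
) -> list[str]:
    """Collect proband term ids from CLI flags and/or a phenopacket-style JSON.

    In the JSON form, term ids come from the subject's phenotypic-feature
    entries; features flagged excluded/negated are skipped.  Returns the
    deduplicated ids in input order; raises if none remain or a CURIE is
    malformed.
    """
    collected: list[str] = list(terms)
    if phenopacket_path is not None:
        with open(phenopacket_path) as fh:
            packet = json.load(fh)
        for feature in packet.get("phenotypicFeatures", []):
            if feature.get("excluded") or feature.get("negated"):
                continue
            term_id = feature.get("type", {}).get("id")
            if term_id:
                collected.append(term_id)
    malformed = [t for t in collected if not _CURIE_RE.match(t)]
    if malformed:
        raise ValueError(f"malformed term ids (expected CURIEs): {malformed}")
    seen: dict[str, None] = {}
    for t in collected:
        seen.setdefault(t)
    if not seen:
        raise ValueError("at least one phenotype term is required")
    return list(seen)


@dataclass
class RunSummary:
    parsed: int = 0
    skipped: int = 0
    depth_filtered: int = 0
    frequency_filtered: int = 0
    scored: int = 0
    removal_log: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "parsed": self.parsed,
            "skipped": self.skipped,
            "depth_filtered": self.depth_filtered,
            "frequency_filtered": self.frequency_filtered,
            "scored": self.scored,
        }


def prioritize_variants(
    variants,
    genes: Sequence[ann.GeneModel],
    query: phenotype.Query,
    disease_models: dict[str, phenotype.DiseaseModel],
    ic_table: phenotype.ICTable,
    config: Config = Config(),
) -> list[PrioritizedVariant]:
    """Score and rank already-filtered harmonized variants."""
    index = ann.GeneIndex(genes, config.promoter_length)
    scored = []
    for v in variants:
        gene_results = []
        for gene in index.genes_for_variant(v):
            delta = gene_delta(v, gene, config.promoter_length, config.splice_width)
            disease_id, phi_value = phenotype.best_disease_phi(
                query, gene, disease_models, ic_table
            )
            gene_results.append((gene.gene_id, delta.delta, phi_value, disease_id))
        scored.append(psv_score(v, gene_results))
    return rank_variants(scored)


def run_prioritize(
    vcf_path: str | Path,
    transcripts_path: str | Path,
    panel_paths: Sequence[str | Path],
    obo_path: str | Path,
    disease_annotations_path: str | Path,
    gene_disease_path: str | Path,
    hpo_terms: Sequence[str],
    out_prefix: str | Path,
    config: Config = Config(),
) -> tuple[list[PrioritizedVariant], RunSummary]:
    """The full pipeline; writes ``<out_prefix>.tsv`` and ``<out_prefix>.vcf``."""
    genes = ann.load_transcripts(transcripts_path)
    ann.load_gene_diseases(gene_disease_path, genes)
    contigs = {g.contig.name: g.contig for g in genes}

    ontology = phenotype.load_obo(obo_path)
    diseases = phenotype.load_disease_annotations(disease_annotations_path, ontology)
    disease_models = {d.disease_id: d for d in diseases}
    ic_table = phenotype.compute_ic(ontology, diseases)
    query = phenotype.make_query(hpo_terms, ontology)

    panels = []
    for p in panel_paths:
        p = Path(p)
        if p.suffix.lower() in (".vcf", ".gz", ".bcf"):
            panels.append(ann.load_common_sv_vcf(p, contigs))
        else:
            panels.append(ann.load_common_sv_tsv(p, contigs))

    read = vcf_io.read_vcf(
        vcf_path,
        assembly=contigs,
        dialect=config.caller_dialect,
        pass_only=config.pass_only,
    )
    summary = RunSummary(
        parsed=len(read.variants), skipped=len(read.skipped)
    )
    if not read.variants:
        raise ValueError(f"no parseable structural variants in {vcf_path}")

    depth = filtering.depth_filter(read.variants, config.min_read_support)
    summary.depth_filtered = len(depth.removed)
    freq = filtering.frequency_filter(
        depth.kept,
        panels,
        config.frequency_threshold,
        config.overlap_threshold,
        config.ins_padding,
    )
    summary.frequency_filtered = len(freq.removed)
    summary.removal_log = [(v.id, reason) for v, reason in depth.removed + freq.removed]

    ranked = prioritize_variants(
        freq.kept, genes, query, disease_models, ic_table, config
    )
    summary.scored = len(ranked)

    out_prefix = Path(out_prefix)
    vcf_io.write_results(
        ranked, out_prefix.with_suffix(".tsv"), out_prefix.with_suffix(".vcf"), contigs
    )
    logger.info(
        "parsed=%d skipped=%d depth_filtered=%d frequency_filtered=%d scored=%d",
        summary.parsed, summary.skipped, summary.depth_filtered,
        summary.frequency_filtered, summary.scored,
    )
    return ranked, summary
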
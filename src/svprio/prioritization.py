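"""Combine δ(g) and Φ(Q, D) into the PSV score and rank variants.

The Pathogenicity of Structural Variation score for a variant affecting
genes G is

    PSV(Q, G, D) = Σ_{g ∈ G} δ(g) · e^{Φ(Q, D_g)}

where D_g is the gene's best-matching disease model.  The score is
additive over genes and monotone in every δ and Φ; with no phenotype
match anywhere (all Φ = 0) it reduces to Σ δ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .genome import HarmonizedVariant, SvType


@dataclass(frozen=True)
class GeneContribution:
    gene_id: str
    delta: float
    phi: float
    disease_id: Optional[str]

    @property
    def contribution(self) -> float:
        return self.delta * math.exp(self.phi)


@dataclass
class PrioritizedVariant:
    variant: HarmonizedVariant
    psv: float
    contributions: list[GeneContribution] = field(default_factory=list)
    rank: int = 0
    median_rank: float = 0.0  # tie-aware middle-of-group rank


def psv_score(
    variant: HarmonizedVariant,
    gene_results: list[tuple[str, float, float, Optional[str]]],
) -> PrioritizedVariant:
    """Score one variant from per-gene (gene_id, δ, Φ, disease) tuples.

    For a breakend record the genes of both breakends are passed in
    together: one PSV per VCF record.  An empty gene list scores 0.
    """
    contributions = [
        GeneContribution(gene_id, delta, phi_value, disease_id)
        for gene_id, delta, phi_value, disease_id in gene_results
    ]
    contributions.sort(key=lambda c: (-c.contribution, c.gene_id))
    total = sum(c.contribution for c in contributions)
    return PrioritizedVariant(variant, total, contributions)


def _sort_key(pv: PrioritizedVariant):
    v = pv.variant
    if v.region is not None:
        contig, start = v.region.contig.name, v.region.start
    else:
        contig, start = v.adjacency.left.contig.name, v.adjacency.left.position
    return (-pv.psv, contig, start, v.id)


def rank_variants(scored: list[PrioritizedVariant]) -> list[PrioritizedVariant]:
    """Order by descending PSV; ties broken by (contig, start, id).

    Each variant receives a 1-based positional rank under the
    deterministic order, plus a tie-aware ``median_rank`` equal to the
    middle position of its tied group (the convention used when a
    benchmark reports the rank of a variant inside a tied block).
    """
    ordered = sorted(scored, key=_sort_key)
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].psv == ordered[i].psv:
            j += 1
        group_median = (i + 1 + j) / 2  # median of positions i+1 .. j
        for k in range(i, j):
            ordered[k].rank = k + 1
            ordered[k].median_rank = group_median
        i = j
    return ordered
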
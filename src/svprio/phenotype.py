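"""Ontology handling, information content, and the symmetric Resnik
phenotype similarity Φ(Q, D).

The ontology is a rooted DAG of phenotype terms with is_a edges.  The
information content of a term is its negative log annotation frequency
across the disease corpus, IC(t) = −ln(n_t / N), where n_t counts the
diseases annotated (directly or via a descendant) with t and N is the
corpus size.  The similarity of two terms is the IC of their most
informative common ancestor (MICA); the similarity of a query Q to a
disease D averages, over each side's own terms, the best term-pair
match, and Φ is the mean of the two directed similarities:

    Φ(Q, D) = ( sim(Q→D) + sim(D→Q) ) / 2
    sim(A→B) = (1/|A|) Σ_{a∈A} max_{b∈B} IC(MICA(a, b))

Φ is symmetric and bounded by the largest IC in the corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet


@dataclass
class Ontology:
    """A rooted DAG of terms with child → parents (is_a) edges."""

    parents: dict[str, frozenset[str]]
    root: str
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents or term in self.aliases

    def resolve(self, term: str) -> str:
        """Map alt/obsolete ids to the primary id; raise on unknown terms."""
        if term in self.parents:
            return term
        if term in self.aliases:
            return self.aliases[term]
        raise KeyError(f"term {term!r} not in ontology")

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term``, including the term itself."""
        term = self.resolve(term)
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = [term]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def validate(self) -> None:
        graph = nx.DiGraph(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        graph.add_nodes_from(self.parents)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology contains an is_a cycle")
        for term in self.parents:
            if self.root not in self.ancestors(term):
                raise ValueError(f"term {term} does not reach the root {self.root}")


def load_obo(path: str | Path, root: Optional[str] = None) -> Ontology:
    """Read an OBO file (is_a edges only) into an :class:`Ontology`.

    Obsolete terms and alt_ids are resolved through an alias map.
    """
    graph = obonet.read_obo(str(path))
    parents: dict[str, frozenset[str]] = {}
    aliases: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        parents[node] = frozenset(
            v for _u, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        for alt in data.get("alt_id", []):
            aliases[alt] = node
        replaced = data.get("replaced_by")
        if replaced:
            aliases[node] = replaced[0]
    if root is None:
        roots = [t for t, ps in parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"cannot infer a unique root (candidates: {roots})")
        root = roots[0]
    onto = Ontology(parents, root, aliases)
    onto.validate()
    return onto


@dataclass(frozen=True)
class DiseaseModel:
    disease_id: str
    annotations: frozenset[str]

    def __post_init__(self) -> None:
        if not self.annotations:
            raise ValueError(f"disease {self.disease_id} has no annotations")


@dataclass(frozen=True)
class Query:
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("query must contain at least one term")


def make_query(term_ids: Iterable[str], ontology: Ontology) -> Query:
    """Build a deduplicated query, rejecting ids absent from the ontology."""
    resolved = set()
    unknown = []
    for t in term_ids:
        try:
            resolved.add(ontology.resolve(t))
        except KeyError:
            unknown.append(t)
    if unknown:
        raise ValueError(f"unknown phenotype term ids: {', '.join(sorted(unknown))}")
    return Query(frozenset(resolved))


def load_disease_annotations(
    path: str | Path, ontology: Ontology
) -> list[DiseaseModel]:
    """TSV (disease_id, term_id) pairs → disease models; unknown terms rejected."""
    by_disease: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            disease_id, term_id = line.split("\t")[:2]
            by_disease.setdefault(disease_id, set()).add(ontology.resolve(term_id))
    return [
        DiseaseModel(d, frozenset(terms)) for d, terms in sorted(by_disease.items())
    ]


class ICTable:
    """Term → information content, with a MICA-IC pair cache.

    IC is in nats; the root (and any term annotating every disease) has
    IC = 0.  Terms annotating no disease receive a pseudo-count of one
    disease, i.e. IC = ln N, so that queries using them stay finite.
    """

    def __init__(self, ic: dict[str, float], ontology: Ontology):
        self.ic = ic
        self.ontology = ontology
        self._pair_cache: dict[frozenset[str], float] = {}

    def __getitem__(self, term: str) -> float:
        return self.ic[self.ontology.resolve(term)]

    def mica_ic(self, t1: str, t2: str) -> float:
        """IC of the most informative common ancestor (self-inclusive)."""
        t1 = self.ontology.resolve(t1)
        t2 = self.ontology.resolve(t2)
        key = frozenset((t1, t2))
        cached = self._pair_cache.get(key)
        if cached is not None:
            return cached
        common = self.ontology.ancestors(t1) & self.ontology.ancestors(t2)
        value = max(self.ic[t] for t in common)
        self._pair_cache[key] = value
        return value

    def precompute_pairs(self, terms: Iterable[str]) -> None:
        """Warm the pair cache for all pairs of ``terms``."""
        terms = sorted({self.ontology.resolve(t) for t in terms})
        for i, t1 in enumerate(terms):
            for t2 in terms[i:]:
                self.mica_ic(t1, t2)


def compute_ic(ontology: Ontology, diseases: Iterable[DiseaseModel]) -> ICTable:
    """Annotation-frequency IC over the disease corpus.

    Each disease contributes its annotation closure (terms plus all
    their ancestors) once; n_t is the number of diseases whose closure contains
    t, and IC(t) = −ln(n_t / N).
    """
    diseases = list(diseases)
    n = len(diseases)
    if n == 0:
        raise ValueError("cannot compute IC over an empty disease corpus")
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for d in diseases:
        closure: set[str] = set()
        for t in d.annotations:
            closure |= ontology.ancestors(t)
        for t in closure:
            counts[t] += 1
    ic = {
        t: -math.log(max(c, 1) / n) for t, c in counts.items()
    }
    return ICTable(ic, ontology)


def sim_one_sided(
    a_terms: frozenset[str], b_terms: frozenset[str], ic_table: ICTable
) -> float:
    """Average over A's terms of the best MICA-IC against B's terms."""
    total = 0.0
    for a in a_terms:
        total += max(ic_table.mica_ic(a, b) for b in b_terms)
    return total / len(a_terms)


def phi(query: Query, disease: DiseaseModel, ic_table: ICTable) -> float:
    """Symmetric Resnik similarity Φ(Q, D)."""
    return 0.5 * (
        sim_one_sided(query.terms, disease.annotations, ic_table)
        + sim_one_sided(disease.annotations, query.terms, ic_table)
    )


def best_disease_phi(
    query: Query,
    gene,  # GeneModel
    disease_models: dict[str, DiseaseModel],
    ic_table: ICTable,
) -> tuple[Optional[str], float]:
    """The gene's best-matching disease and its Φ.

    A gene with no associated disease has Φ = 0, so its PSV weight is
    e^0 = 1: a disrupted but phenotypically irrelevant gene still
    contributes its raw δ.
    """
    best: tuple[Optional[str], float] = (None, 0.0)
    for disease_id in gene.disease_ids:
        model = disease_models.get(disease_id)
        if model is None:
            continue
        value = phi(query, model, ic_table)
        if value > best[1] or (value == best[1] and best[0] is None):
            best = (disease_id, value)
    return best
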
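"""Information content and symmetric Resnik similarity Φ(Q, D).

Builds the toy phenotype ontology and disease corpus, computes the
annotation-frequency information content of each term, and compares a
proband's term set against two disease models.
"""

import math

from svprio import DiseaseModel, Query, compute_ic, phi
from svprio.phenotype import Ontology

# a small rooted DAG: root -> {nervous, skeletal}; leaves below each
parents = {
    "HP:R": frozenset(),
    "HP:NERV": frozenset({"HP:R"}),
    "HP:SKEL": frozenset({"HP:R"}),
    "HP:SEIZ": frozenset({"HP:NERV"}),
    "HP:ATAX": frozenset({"HP:NERV"}),
    "HP:SCOL": frozenset({"HP:SKEL"}),
}
onto = Ontology(parents, root="HP:R")
onto.validate()

diseases = [
    DiseaseModel("OMIM:1", frozenset({"HP:SEIZ", "HP:ATAX"})),
    DiseaseModel("OMIM:2", frozenset({"HP:SEIZ"})),
    DiseaseModel("OMIM:3", frozenset({"HP:SCOL"})),
    DiseaseModel("OMIM:4", frozenset({"HP:SCOL"})),
]
ic = compute_ic(onto, diseases)

print("term information content, IC(t) = -ln(n_t / N), N = 4 diseases:")
for term in parents:
    print(f"  IC({term:8s}) = {ic[term]:.4f}")

query = Query(frozenset({"HP:SEIZ", "HP:ATAX"}))
for d in (diseases[0], diseases[2]):
    value = phi(query, d, ic)
    print(f"\nΦ(proband, {d.disease_id}) = {value:.4f}"
          f"   (e^Φ weight = {math.exp(value):.2f})")

print(
    "\nA proband with seizures and ataxia matches the neurological "
    "disease exactly (Φ equals the mean IC of its terms) and the "
    "skeletal disease only at the root (Φ = 0, weight 1): phenotype "
    "match multiplies a disrupted gene's score by e^Φ."
)
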
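"""The full pipeline: read a proband VCF, filter, score, rank, write.

Generates a 150-variant neutral background, spikes in a causal in-frame
exon deletion of the phenotype-matched gene G01, and runs the complete
prioritization, printing the stage counts and the top of the ranking.
"""

import tempfile
from pathlib import Path

from svprio import run_prioritize
from svprio import synthetic as syn

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    world = syn.make_toy_annotation(0)
    resources = syn.write_world(world, tmp / "resources")

    gene = world.gene("G01")
    s = gene.span().start
    causal = syn.symbolic_record(
        "causal_del", "DEL", "chr1", s + 4_990, s + 5_154,
        alt_depth=5, ref_depth=5,
    )
    background = syn.make_background_vcf(150, seed=11, world=world)
    vcf = tmp / "proband.vcf"
    vcf.write_text(background + causal)

    ranked, summary = run_prioritize(
        vcf,
        resources["transcripts"],
        [resources["panel"]],
        resources["obo"],
        resources["disease_annotations"],
        resources["gene_disease"],
        hpo_terms=world.disease_terms_for_gene("G01"),
        out_prefix=tmp / "out",
    )

    print("stage counts:", summary.as_dict())
    print("\ntop 5 of the ranking:")
    for pv in ranked[:5]:
        genes = ",".join(c.gene_id for c in pv.contributions) or "-"
        print(f"  rank {pv.rank:3d}  PSV {pv.psv:8.4f}  "
              f"{pv.variant.sv_type.value:3s}  {pv.variant.id:12s} genes={genes}")

    tsv_lines = (tmp / "out.tsv").read_text().splitlines()
    print(f"\nwrote {len(tsv_lines) - 1} rows to out.tsv and an annotated "
          f"out.vcf with PSV/RANK INFO fields")

print(
    "\nThe spiked-in deletion (δ = 0.8 for an in-frame exon loss, "
    "weighted by e^Φ for the matching disease) takes rank 1; the common "
    "and low-support background calls are removed by the filters, and "
    "the neutral remainder scores 0."
)
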
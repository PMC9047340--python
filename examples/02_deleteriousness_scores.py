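"""Per-gene sequence deleteriousness δ(g) for different SV placements.

Uses the built-in toy gene G01 (three exons: a 100-bp 5'UTR, a 144-bp
in-frame middle coding exon, a 200-bp 3'UTR) and scores a panel of
variants against it.
"""

from svprio import GenomicRegion, HarmonizedVariant, SvType, gene_delta
from svprio.synthetic import make_toy_annotation

world = make_toy_annotation(0)
gene = world.gene("G01")
chr1 = world.contigs["chr1"]
S = gene.span().start  # 100000

cases = [
    ("whole-gene deletion", SvType.DEL, S - 500, S + 11_000, {}),
    ("in-frame loss of the 144-bp exon", SvType.DEL, S + 4_990, S + 5_154, {}),
    ("frameshifting intra-exon deletion (32 bp)", SvType.DEL, S + 5_010, S + 5_042, {}),
    ("deletion of half the 3'UTR", SvType.DEL, S + 9_800, S + 9_900, {}),
    ("deep intronic deletion", SvType.DEL, S + 1_000, S + 1_500, {}),
    ("promoter deletion", SvType.DEL, S - 1_500, S - 500, {}),
    ("whole-gene duplication", SvType.DUP, S - 100, S + 10_100, {}),
    ("whole-gene triplication", SvType.CNV, S - 100, S + 10_100, {"gain": 2}),
    ("tandem dup of the final exon", SvType.DUP, S + 9_500, S + 10_500, {}),
    ("inversion containing the gene", SvType.INV, S - 500, S + 11_000, {}),
    ("inversion breaking exon 1", SvType.INV, S - 500, S + 200, {}),
    ("35-bp coding insertion", SvType.INS, S + 5_050, None, {"ins": 35}),
    ("36-bp coding insertion", SvType.INS, S + 5_050, None, {"ins": 36}),
]

print(f"gene {gene.gene_id} at {chr1.name}:{S}-{S + 10_000}\n")
for label, sv_type, start, end, kw in cases:
    if sv_type is SvType.INS:
        v = HarmonizedVariant(
            "v", sv_type, region=GenomicRegion(chr1, start, start),
            ins_length=kw["ins"],
        )
    else:
        v = HarmonizedVariant(
            "v", sv_type, region=GenomicRegion(chr1, start, end),
            copy_number_gain=kw.get("gain", 1),
        )
    print(f"  δ = {gene_delta(v, gene).delta:4.2f}  {label}")

print(
    "\nδ = 1 marks predicted loss of transcript function, 0.8 an in-frame "
    "exon loss, 0.9/0.2 frameshift/in-frame insertions, 0.4 a promoter "
    "hit (40% of a coding hit), and 0 a presumed-neutral placement; "
    "full-gene copy gains score one per extra copy."
)
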
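"""Decode the three VCF SV notations into one harmonized model.

Builds a four-record VCF in memory — a sequence-notation deletion, a
symbolic inversion, a symbolic insertion, and a breakend — reads it
back, and prints the notation-independent form of each call.
"""

import tempfile
from pathlib import Path

from svprio import read_vcf

VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tproband
chr1\t100\tseq_del\tACGT\tA\t.\tPASS\t.\tGT:AD\t0/1:6,9
chr1\t5000\tsym_inv\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=5800\tGT:AD\t0/1:7,7
chr1\t9000\tsym_ins\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=120\tGT:AD\t0/1:8,5
chr1\t20000\tbnd\tN\tN[chr2:333333[\t.\tPASS\tSVTYPE=BND\tGT:AD\t0/1:5,5
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "calls.vcf"
    path.write_text(VCF)
    result = read_vcf(path, dialect="pbsv")

print(f"parsed {len(result.variants)} records, skipped {len(result.skipped)}\n")
for v in result.variants:
    if v.adjacency is not None:
        left, right = v.adjacency.left, v.adjacency.right
        where = (f"{left.contig.name}:{left.position + 1} <-> "
                 f"{right.contig.name}:{right.position + 1}")
    else:
        where = f"{v.region.contig.name}:[{v.region.start}, {v.region.end})"
    extra = f" ins_length={v.ins_length}" if v.ins_length else ""
    print(f"{v.id:8s} {v.sv_type.value:3s} {where}{extra} "
          f"alt_reads={v.alt_read_count} gt={v.genotype.value}")

print(
    "\nEach line is one harmonized variant: internal coordinates are "
    "0-based half-open; an insertion is a zero-length anchor plus its "
    "inserted length; a breakend is an adjacency of two stranded positions."
)
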
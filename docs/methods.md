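# Methods

## Variant model and coordinates

All internal coordinates are 0-based half-open on the forward strand;
VCF I/O converts at the boundary. Every call is harmonized into one of
two shapes: a typed genomic region (DEL, DUP, INS, INV, CNV) or a single
adjacency of two stranded breakends (BND). Insertions carry a
zero-length anchor region at the insertion point plus the inserted
length; copy-number records carry a `copy_number_gain` (1 for a plain
duplication, CN−2 for a CNV with an explicit copy number, floored at 1).
Each breakend record is treated as an independent adjacency — records
are never grouped by their EVENT tag, so a reciprocal translocation
contributes two scored records.

Decoding rules per notation:

- **Sequence** (REF/ALT both literal): net loss of bases is a deletion
  of the unshared REF suffix; net gain is an insertion anchored after
  the shared prefix. Length-preserving records (SNV/MNV) are not
  structural variants and are skipped with a logged warning.
- **Symbolic** (`<DEL>` etc.): when SVLEN is present it fixes the region
  length from POS; otherwise the record spans [POS, END] 1-based
  inclusive. SVLEN wins over END because htslib folds END into the
  record's computed stop and itself prefers SVLEN for symbolic alleles,
  so a raw END cannot be recovered once both are present; the writer
  emits both fields consistently, making write→read round-trips exact.
  SVLEN signs are normalized (absolute value).
- **Breakend**: bracket ALTs are parsed into (contig, position, strand)
  pairs; the local side is `+` when the anchor base precedes the
  bracket, and the mate side is `+` for `[` (joined to sequence
  extending rightward) and `−` for `]`. Malformed brackets or unknown
  mate contigs skip the record with a warning.

Only the first ALT of a multi-allelic record is processed (logged).
Skipped records are counted so that parsed + skipped equals the input
record count.

ALT-supporting read depth is caller-specific: `pbsv` reports FORMAT
`AD` (ref,alt), `sniffles` FORMAT `DV` (INFO `RE` as fallback), and
`SVIM` INFO `SUPPORT` (FORMAT `AD` as fallback). The `auto` dialect
probes those in order. The field map is configurable because callers
change their conventions between versions; absent depth is a legal
state and never removes a variant.

## Filtering

A region variant is removed when any panel entry of a matching SV class
(DEL↔DEL, DUP↔DUP/CNV, INV↔INV, INS↔INS) has allele frequency strictly
above the frequency threshold (default 0.01) and reciprocal overlap —
min(ov/len(a), ov/len(b)) — strictly above the overlap threshold
(default 0.80). Both inequalities are strict, mirroring the "more than
1%" / "greater than 80%" convention, and both thresholds are
user-adjustable. Panels combine with OR semantics. Cross-class overlap
matching is biologically meaningless and is not attempted; whether DUP
should also match CNV gains was an open choice, resolved as yes and
kept configurable in code.

Reciprocal overlap is undefined for zero-length insertion anchors, so
two insertions match when their anchors lie within a padding window
(default 100 bp) and their length ratio min/max exceeds the overlap
threshold. Breakend records are never frequency-filtered.

The depth filter removes calls whose ALT support is known and below 3
reads; unknown support is kept. Filtering is order-independent and
conserves counts (kept + removed = input), and raising either threshold
can only shrink the removed set — all three properties are tested.

## Deleteriousness δ(g)

For each gene the variant touches, every transcript is classified and
scored; the gene takes the maximum transcript score. Classification
resolves the variant against the transcript's elements with precedence
coding/splice > TSS > UTR > promoter > intron (the most deleterious
applicable rule wins). The promoter is the 2 kb immediately upstream of
the transcript's TSS on its strand (clipped at contig bounds; default
configurable), derived per transcript since isoforms may start at
different positions. The splice region is the 2 intronic bases flanking
each exon boundary (configurable; the canonical donor/acceptor
dinucleotides).

Scores per class:

| class | t ⊂ SV | t ⇌ SV | ⊂ coding/splice | ⊂ UTR | ⊂ intron | ⊂ promoter |
|-------|--------|--------|------------------|-------|----------|------------|
| DEL   | 1      | 1      | {0.8, 1}         | Eq. below | 0    | 0.4        |
| DUP   | gain   | 0      | 1                | Eq. below | 0    | 0.4        |
| INV   | 0      | 1      | 1                | Eq. below | 0    | 0.4        |
| INS   | –      | –      | {0.2, 0.9}       | Eq. below | 0    | 0.4        |
| BND   | –      | –      | 1                | 1     | 1        | 0.4        |

UTR deletions/duplications score min(2·len_SV/len_UTR, 1) and UTR
insertions min(len_INS/len_UTR, 1), where len_SV is the intersection of
the variant with the UTR's exonic bases (a variant extending past the
UTR into coding sequence is already governed by the coding rule through
precedence) and len_UTR is the transcript's total exonic length of that
UTR. 5′ and 3′ UTRs score identically. Both formulas depend only on the
length ratio (scale-invariant) and saturate at 1 — a deletion of half
the UTR, or an insertion as long as the UTR, already scores maximally.

Frame resolution for deletions: the deleted coding length modulo 3
decides in-frame (0.8) versus frameshift (1) when the deletion removes
whole exons or stays inside one exon; a deletion that breaks a splice
junction asymmetrically (part of an exon plus flanking intron, or a
splice region without coding bases) is frameshift-equivalent and scores
1. Insertions use the inserted length modulo 3; an insertion landing in
a splice region is treated as a frameshifting coding hit (0.9) — the
boundary case is not specified anywhere authoritative, and the
conservative reading was chosen. Exonic hits in non-coding transcripts
score as transcript-disrupting (1 for deletions/inversions) since no
frame is defined.

Special cases: loss of the TSS (the first transcribed base) is as
deleterious as a coding hit (1) for deletions. A duplication that
partially overlaps the transcript while extending beyond its 5′ or 3′
terminus is neutral (0): the tandem copy is appended outside the
primary transcript, leaving its linear sequence intact. An inversion
containing the whole transcript is neutral for the same reason, while
any inversion breakend inside the transcript scores 1, as does an
inversion covering some but not all exons; one wholly inside a UTR exon
falls back to the UTR formula (the rule table carries a UTR column for
inversions even though the prose only discusses breakpoints). Breakends
score 1 anywhere inside a transcript — coding, UTR, or intron — and 0.4
in the promoter; both ends of an adjacency are scored and a record's
gene set is the union over both ends.

## Phenotype similarity Φ(Q, D)

The ontology is a rooted DAG of terms with is_a edges (read from OBO;
alt/obsolete ids resolve through an alias map; unknown query ids are a
hard error listing the offenders, never silently dropped). Information
content is the annotation frequency over the disease corpus:
IC(t) = −ln(n_t/N) in nats, with n_t the number of diseases annotated
with t or any descendant. Natural log is the right base because the PSV
score exponentiates Φ with base e. Terms annotating no disease receive
a pseudo-count of one disease (IC = ln N) so queries using them stay
finite. IC(root) = 0 and IC is monotone non-decreasing from root to
leaf.

Φ is the symmetric Resnik best-match average: each side averages, over
its own terms, the best IC(MICA) against the other side, and Φ is the
mean of the two directions. The printed form of the one-sided sum in
the source description normalizes ambiguously (1/m against a sum over
query terms); the standard symmetric reading — each direction
normalized by its own term count — is implemented, which makes Φ
symmetric by construction. Φ(Q,Q) ≥ Φ(Q,D) is *not* an invariant of
best-match averaging and is not asserted; the enforced bound is
Φ ≤ max IC over the corpus. Pairwise MICA values are cached and may be
precomputed; the cache provably agrees with on-the-fly computation
(tested exhaustively on the toy ontology).

A gene with several diseases uses the best-matching one; a gene with no
disease has Φ = 0 and therefore weight e⁰ = 1, so a disrupted but
phenotypically irrelevant gene still contributes its raw δ.

## PSV score and ranking

PSV(Q,G,D) = Σ_{g∈G} δ(g)·e^{Φ(Q,D_g)} over the genes the variant
affects; an intergenic variant's G is its nearest upstream and
downstream genes (which then score δ = 0 unless a promoter is hit), and
an empty G scores 0. The score is additive over genes and monotone in
every δ and Φ; with no phenotype information it reduces to Σδ.
Variants are ranked by descending PSV with deterministic tie-breaking
by (contig, start, id); alongside the positional rank, a tie-aware
median-of-group rank is reported (tied variants all receive the middle
position of their block), the convention benchmarks use when the causal
variant sits inside a tied group.

## Synthetic data and the spike-in benchmark

`svprio.synthetic` generates every input format the pipeline consumes.
The toy world is fixed (seed-independent, hence trivially reproducible):
three contigs (2 Mb/1 Mb/0.5 Mb), twelve genes with a shared three-exon
layout — 100-bp 5′UTR, a 144-bp in-frame middle coding exon, 200-bp
3′UTR, multi-kilobase introns — including minus-strand genes, a
non-coding gene, a two-isoform gene (exercising the max-over-transcripts
rule), and an adjacent pair for intergenic lookups. The ontology is a
36-term rooted DAG (5 branches × 2 mid terms × 2 leaves), annotated to 8
disease models of 3–4 terms each; nine genes carry a disease link. A
common-SV panel holds intergenic entries at 2–8% allele frequency plus
one rare (0.5%) entry that must never trigger the filter.

Background call sets are parameterized by seed and size: a mix of all
five SV classes and all three notations, with pbsv-style depth fields.
Neutrality is enforced by construction — region variants are placed deep
inside introns (≥ 500 bp from any exon) or in intergenic windows at
least 3 kb from any gene span, breakends are intergenic at both ends
(a breakend inside an intron would legitimately score 1), ~10% of
variants copy a common panel entry (removed by the frequency filter),
and ~5% carry ALT support below 3 reads (removed by the depth filter).
This construction is what makes rank-1 recovery a valid oracle.

Spike-in cases place a deleterious variant (in-frame exon deletion
δ=0.8, whole-gene duplication δ=1, 35-bp coding insertion δ=0.9,
transcript-breaking inversion δ=1, or coding translocation breakend
δ=1) in a disease-linked gene, with the proband query set to that
disease's terms and allelic depth 5:5 so the causal call survives the
depth filter. The benchmark inserts each case into fresh neutral
backgrounds, runs the full pipeline per background, and records the
median tie-aware rank; a causal variant lost to filtering is reported
with an infinite sentinel. The default suite — 20 cases cycling through
the five classes, 3 backgrounds of 120 variants per case — runs in a few
seconds on one core; sizes are deliberate desk-scale choices, large
enough to exercise every filter and class and small enough to iterate
on.

What passing does and does not show: the generator emulates the
*structure* of long-read call sets (class and notation mix, caller depth
fields, common-variant contamination), not their realism — no sequencing
error profile, no call-rate variation, no multi-gene disease loci, an
ontology orders of magnitude smaller than a real phenotype ontology,
and backgrounds that are neutral by design rather than empirically.
Rank-1 recovery here validates the plumbing and the score's ordering
behaviour, not clinical performance on real genomes. Absolute Φ values
(and hence PSV magnitudes) always depend on the disease corpus used to
compute IC, so composite-score checks fix δ and Φ as inputs and verify
the arithmetic.

## Numerical and degenerate-input choices

Reciprocal overlap of a zero-length region is defined as 0 (insertions
are matched by position and length instead). Distance between abutting
half-open intervals is 0 with `overlaps` false. A variant on a contig
with no annotated gene scores 0 but is still reported. A promoter is
clipped at contig bounds, so a gene starting within 2 kb of a contig
end has a shortened promoter. Scores are exact rationals in floating
point (no iterative numerics anywhere); the pipeline contains no
randomness, and two runs on identical inputs produce byte-identical
TSV output.

## Known limitations

No nucleotide-level consequence calling (HGVS), splice-strength or
regulatory models; enhancer/repeat/dosage tracks are carried as
annotations only and never enter the score. No mode-of-inheritance or
compound-heterozygote logic; multi-sample VCFs use the first sample
only; multi-allelic records use the first ALT. Frequency filtering does
not stratify by population, and breakends are never frequency-filtered
at all — a common translocation polymorphism would survive to scoring.
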
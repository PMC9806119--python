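# Methods

This note documents the statistical procedures, conventions and design
choices behind `splicefidelity`, and what the synthetic-data generator does
and does not emulate.

## Coordinates and junction identity

All genomic coordinates are 1-based and fully inclusive, matching both GTF
and the STAR `SJ.out.tab` dialect. A splice junction is identified by
`(contig, first intronic base, last intronic base, strand)`. The donor is
the intron boundary at the 5' end in transcript orientation — on the minus
strand this is the larger genomic coordinate — and all donor/acceptor site
sets are strand-aware. STAR motif codes 1 (GT/AG) and 2 (CT/AC) are treated
as the canonical GT-AG pattern on the plus and minus strand respectively;
rows with undetermined strand are resolved from a canonical motif when
possible and otherwise left unclassified.

A junction overlapping several gene spans is assigned to the same-strand
overlapping gene with the highest TPM (ties break to the smallest gene_id).
Requiring same-strand overlap is a choice of this package; junction
assignment by plain positional overlap is the obvious alternative and would
differ only for antisense-overlapping gene pairs.

## Unannotated-junction selection

Within each robustly expressed gene (TPM > 10, strict), let D be the
maximum unique-read count over the gene's *annotated* junctions observed in
the sample. Canonical unannotated junctions with reads >= 0.1·D are kept
("at least 10%" is read as inclusive; the TPM gate as strict). D comes from
the sample's observed reads, not from the annotation alone: genes whose
annotated junctions all have zero observed reads are skipped, since a
denominator of zero would keep everything. Single-exon genes are excluded
outright (no annotated junction exists to define D). Both the fraction
(default 0.1) and the TPM gate (default 10) are configurable for
sensitivity analyses. Multi-replicate consistency is the intersection of
the per-replicate flagged-gene sets.

The per-sample summary statistic divides the flagged genes by the eligible
genes: multi-exon, above the TPM gate, with >= 1 observed annotated
junction. Requiring an observed annotated junction (rather than all TPM>10
genes) is deliberate — a gene in which the filter could not run should not
sit in the denominator.

## Inclusion level, commitment, differential tests

The inclusion level uses junction-only counting with effective lengths 2
(two inclusion junctions) and 1 (one skipping junction):
`psi = (I/2) / (I/2 + S)`. Events with I + S below a configurable floor
(default 10) are excluded from commitment scoring, so psi estimates from a
handful of reads cannot masquerade as committed exons; the floor's exact
value is a judgment call recorded in the run manifest. Duplicate skipped
exons (the same exon removed by different junction pairs) collapse to the
minimum psi. The commitment score is `(#{psi > 0.99} + #{psi < 0.01}) /
total` with strict inequalities at both bounds.

Differential exon usage pools replicate counts per condition and applies a
two-sided Fisher exact test to the 2x2 table (I1, S1; I2, S2), with
Benjamini-Hochberg correction across events. This replaces a hierarchical
event-level likelihood model (as in rMATS) with an exact conditional test:
it ignores between-replicate overdispersion, which makes it anti-
conservative on highly variable replicates, but it is exact, dependency-
free and transparent. FDR gates: 0.05 for event sets, 0.0005 for
"high-confidence" junction sets used in cross-dataset overlap comparisons.
Differential intron retention uses the same machinery on rounded
(intronic depth, spliced reads) evidence.

## Intron retention

`IR = mean intronic depth / (mean intronic depth + exact-spanning spliced
reads)`. This is a simplification of IRFinder's trimmed, masked estimator:
it preserves the quantity's meaning (intronic abundance relative to
intronic-plus-spliced) and the downstream thresholding, but applies no
mappability or overlapping-feature masking — coverage tables are expected
to arrive pre-computed (the package does no BAM pileup). Only introns whose
exact-spanning junction is detected in the sample are scorable. A gene is
high-retention when any intron exceeds IR > 0.25 (strict); the denominator
counts expressed genes with >= 1 scorable intron (the variant counting all
expressed genes is a config switch away in the calling code).

## NMD and domain consequences

Frame effect is decided by the skipped exon's CDS-overlapping length modulo
3; exons partially overlapping the CDS contribute only the overlapping
bases. Frame-shifting skips are scanned from the (remapped) start codon;
the first in-frame stop strictly upstream of the remapped annotated stop is
the PTC. The NMD call uses the classical exon-junction-complex distance
rule: PTC more than 50 nt upstream of the **final** exon-exon junction of
the skipped isoform, with distance measured from the last base of the stop
codon to the last base of the exon preceding the junction. A literal
"any junction" variant is available (`junction_rule="any"`); any PTC
satisfying the last-junction rule trivially satisfies it. When several
transcripts contain the skipped exon, each is evaluated and the event rolls
up as NMD-targeting if **any** isoform qualifies, then domain-affecting if
any in-frame isoform overlaps a supplied domain interval, else neither —
each event is counted once.

Domain evidence comes from a local protein-coordinate interval table
(protein id convention: the transcript id) rather than a web-service
domain search; any E-value filtering therefore happens upstream of this
package. The skipped exon's protein span rounds outward to whole codons,
so junction-spanning codons count on both sides. In-frame skips that might
create a novel junction-spanning stop are still routed to domain analysis.

## Overlap statistics

Shared proportion uses |A∩B| / |A∪B|; the wording "divided by the total
number in the two datasets" is ambiguous between union and |A|+|B|, and the
union keeps the statistic in [0,1] with value 1 for identical sets (the sum
convention is a config option). The hypergeometric p-value is the exact
upper tail P(X >= k), summed in log space over the support, accurate to
~1e-12 relative for universes up to 1e6 (validated against exact rational
enumeration for N <= 1000). The universe is the union of eligible keys
across the compared samples for unannotated-junction comparisons, and the
events tested in both comparisons for altered-event comparisons; it is
recorded in every output, because the p-values depend on it.

## Splice-site scorer

Donor sites are scored over a 9-nt window (last 3 exonic + first 6
intronic bases) and acceptors over 23 nt (last 20 intronic + 3 exonic),
matching MaxEntScan's window conventions so externally computed MaxEntScan
scores can be substituted per site. The built-in scorer is a log-odds PWM
(`sum log2(p_model / p_background)`) trained on all annotated junctions
with a pseudocount (default 1) and the genome's overall base composition as
background; `N` positions contribute 0. A PWM ignores positional
dependencies that a maximum-entropy model captures, so absolute scores are
not comparable to MaxEntScan's — within-dataset contrasts (event set vs
annotation baseline) are the supported use. Feature comparisons against
the annotation-wide baseline use a two-sided Mann-Whitney test with
Bonferroni correction across features; the baseline is per-exon (every
annotated internal exon of expressed genes), not per-gene.

## Synthetic data

The generator emulates the study design, not read-level sequencing: genes
with 4-7 exons (exons 60-150 nt, introns 80-250 nt, GT..AG boundaries, 40%
on the minus strand), a clean CDS (ATG, no internal in-frame stops, stop in
the last exon, stop codon included in the CDS features), one designated
skippable internal exon per gene, and a second annotated transcript lacking
that exon so the skipping junction is part of the annotated universe.
Junction depths are negative binomial (mean 120, dispersion 0.1 — standard
RNA-seq overdispersion at this scale); inclusion reads are binomial with
weight `w = 2 psi / (1 + psi)`, which inverts the length-normalised psi
formula so the estimator is unbiased for psi*. Intronic coverage is Poisson
with mean `s·r/(1-r)` given spliced reads s, making the expected IR ratio
equal r*. Injected unannotated junctions (three classes: novel pairing of
annotated sites, hemi-annotated, fully novel) are pinned to 12-50% of the
gene's observed max annotated depth, so the 10% filter keeps them by
construction; their table rows claim canonical motif codes at face value,
like STAR's motif column — the genome is not edited under them.

The bundled two-condition preset encodes the blood-naive-B-cell vs
differentiated-cell contrast: condition A injects unannotated junctions
into 30% of expressed genes with low commitment (35% committed exons,
Beta(1.5,1.5) otherwise) and high retention (Beta(1.3,2.2)); condition B
uses 5%, 90% committed, Beta(0.5,8). Sixty genes, two replicates per
condition — sizes chosen so a full end-to-end run takes seconds while every
per-gene decision is still exercised. NMD boundary fixtures are
constructed, not random: two engineered 4-exon genes place a guaranteed
in-frame stop at exactly 50 and 51 nt upstream of the skipped isoform's
last junction, exercising both sides of the strict >50 rule; their
sequences are built base-by-base with rejection sampling so that neither
reading frame contains an unintended stop.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: alignment artefacts and multimapping,
mappability-biased intronic coverage, nascent-transcript contamination in
non-poly(A) libraries (which inflates apparent retention), overlapping and
antisense genes, alternative 5'/3' splice sites, and between-replicate
biological dispersion beyond the negative binomial depth model.

## Numerical choices and degenerate inputs

psi and IR are undefined (the record is excluded, not zeroed) when their
evidence is all zero. Commitment and retention metrics raise on empty
denominators rather than returning 0. Fisher tables round real-valued
depth evidence to integers. Hypergeometric tails short-circuit to exactly
1.0 at the support's lower edge. All simulation draws flow through one
`numpy` generator seeded from a mandatory seed, so every emitted file is
byte-identical across runs of the same version.
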
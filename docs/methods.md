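# Methods

## Coordinate conventions

All positions live in a single consensus ORF frame per locus class,
1-based and inclusive at both ends: the span 50–725 has length 676 by
`end − start + 1`. Codon *i* occupies positions `3i−2 … 3i`, so the
reading frame is anchored at consensus position 1. Every reference allele
carries a *known interval* — the sub-interval of the frame its deposited
sequence covers — and `len(seq) == known.length` is enforced at
construction. Ambiguity codes (N etc.) are rejected at load: the 100%
identity matching contract is only well-defined over concrete bases.
Known intervals travel in FASTA headers as `known=START-END`, with a
sidecar TSV (name, start, end) as fallback.

## Amplicon geometry

The built-in assay defines HLA-1 (insert 50–725), HLA-2 (145–1069) and
DRB (61–727). The DRB primer windows (61–79, 707–727) are part of the
assay definition; the class I primer windows are nominal 19-nt spans at
the insert ends, since only the insert boundaries are fixed by the assay.
Fusion products add a fixed 35 nt per end (25-nt sequencing adapter +
10-nt MID barcode), giving products of 746/995/737 bp from the three
inserts. Primer *sequences* are not stored in the assay definition: they
are materialised per database as the modal base over the primer window,
computed only from alleles of the amplicon's locus class (pan-locus
conservation holds within class I or within DRB, not across classes).
Per-allele mismatch counts against that consensus are kept on the primer
site, which is how a DRB3-style single-mismatch allele or a
primer-incompatible class I allele is representable.

## Design analysis

The variability profile of an alignment records per column the *depth*
(alleles with a non-gap base) and the *variability* (percentage of
covering alleles differing from the modal base; ties between modal bases
are broken lexicographically so profiles are deterministic). Conserved
windows are maximal runs of columns with variability ≤ 1% and depth ≥ 50%
of alleles, of at least 18 nt — all three thresholds tunable; the
defaults are ordinary primer-design practice, chosen once.

In-silico typing resolution partitions each locus's alleles by sequence
identity over `coverage ∩ known`, comparing two alleles only where both
are known. With partially known alleles this relation is **not
transitive**, so reported groups are connected components of the pairwise
indistinguishability graph: if A≈B and B≈C the assay cannot claim to
separate A from C, even if A and C share no compared position. Pairs with
no comparable position at all are excluded with a warning rather than
guessed. Whether an expression suffix (e.g. `N`) makes two
otherwise-identical names distinct at a given resolution is an explicit
flag (`suffix_distinct`, default true — a null allele is functionally
distinct). Coverage monotonicity (larger coverage ⇒ no new ambiguous
pairs) holds when alleles cover the regions compared; enlarging coverage
into a region where a previously incomparable pair first becomes
comparable can create a pair, which is why the monotonicity property is
stated (and tested) over full-length alleles.

## Read groups, demultiplexing and trimming

A raw read is `MID + gene-specific primer + insert sequence` (reverse
reads carry the reverse complement of the insert). Demultiplexing assigns
a read iff its prefix matches exactly one MID (0 mismatches by default —
generated MIDs are pairwise Hamming ≥ 3 — configurable to 1) and the
following bases match one amplicon primer within 2 mismatches; MID and
primer are clipped and ties or misses land in an unassigned bin with a
reason code. Demultiplexing is a strict partition of the input.

Trimming anchors at the 5′ end after clipping: reads below the group
minimum (default 300 nt) are discarded, reads at or above the target
(default 320 nt) are truncated to it. The operation is idempotent. A
target-length read of group *g* therefore occupies a fixed genomic
window: forward groups start right after the forward primer, reverse
groups end right before the reverse primer. With the default geometry the
class I windows are 1F 69–388, 1R 387–706, 2F 164–483, 2R 731–1050.

## Match conditions and calling

For each (allele, read group) pair the *expected* condition follows from
interval geometry alone: FULL when the known interval contains the
window; EXTEND when the overlap is at least the anchor minimum (30 nt,
configurable — below it a perfect but short overlap is too weak to
distinguish alleles and the condition is NONE) while the read extends
past the known interval; EXTEND_BOTH when it extends past both ends
(typical for exon-2-only DRB references). Observed conditions are
computed identically from the actual read length and must be perfect
(zero mismatches) over the compared region. Reads are clustered by
sequence before mapping — identical reads map identically — and when
reads of different lengths yield different conditions against one allele
the highest-priority condition (FULL > EXTEND_BOTH > EXTEND) is recorded
with the pooled read count.

Typing is keyed: alleles with perfect 2F matches (class I) or any
matching forward condition (class II, where exon-2-only references make
extension matches legitimate keys) form the candidate set; remaining
groups map only against it. The class I matrix inner-joins 2F/1F/1R and
outer-joins 2R; an inner group is exempt for alleles whose expected
condition there is NONE, so short references are not unfairly dropped. An
allele is called when observed row == expected row and every
expected-supporting group has ≥ `min_reads_per_group` reads (default 3;
low-stringency mode accepts ≥ 1 and downgrades confidence unless the
stringent threshold is in fact met).

Called alleles identical over the union of read-group windows *actually
supported in that sample* are merged into a slash-joined ambiguity set —
dropout narrows, never widens, claimed resolution. The reported
resolution of a set is twice the number of leading name fields shared by
all members (0 when even the serological group differs). A locus with
more than two calls is flagged with a warning; a locus with a single call
is marked homozygous-consistent when that call's share of the locus's
matching reads is ≥ 0.8 (triage only — the exported read tables allow
manual review).

Amplicon-discordant detection re-maps amplicon-1 reads against the full
database: an allele absent from the 2F key whose observed amplicon-1
conditions equal its geometry-expected ones (FULL for full-length
references, EXTEND for partial ones), and which is not indistinguishable
from an already-called allele over those windows, is emitted as an
`amplicon_discordant` call instead of being silently missed.

## Novel-allele detection

Identical unmatched reads are clustered per group; clusters of ≥ 3 reads
are compared to every reference by Hamming distance over the aligned
overlap at the group's expected offset (minimum 30 nt overlap). Clusters
within 1–3 SNPs of a reference become candidates; *all* equidistant
nearest references are reported rather than picking one. Candidates from
different read groups with the same nearest references and no conflicting
SNP are merged, pooling support; the candidate's consensus sequence is
the primary nearest reference with the SNPs applied. Each SNP is
annotated with its codon index (`ceil(pos/3)`), reference and alternate
amino acid via the standard genetic code, and a synonymous flag; the
annotation is direction-agnostic — it reports the consequence of the
substitution as given, whichever strand convention named the variant —
and is omitted when the codon is not fully inside the reference's known
interval.

## The simulator

The generator emulates the structural conditions the pipeline assumes:
three loci by default (two class I analogues sharing protected pan-locus
primer sites on a common class consensus, one DRB-style class II locus),
20 alleles per locus at 2% pairwise SNP rate over an 1100-nt frame, 30%
of alleles truncated to an exon-2/3 analogue (104–620) or exon-2 analogue
(100–330), one designed ambiguous twin per locus differing from its
source only 5′ of the sequenced region, 10 diploid samples drawn
uniformly with replacement (twins excluded from truth so the truth table
is recoverable), amplicons pooled 3:6:1 on a base of 300 reads per
amplicon per (sample, locus), 10-nt MIDs at pairwise distance ≥ 3,
optional uniform substitution errors and per-(sample, allele, amplicon)
dropout. Reads are emitted full-amplicon-length and trimmed downstream,
mirroring the trim-to-standard-length step; quality strings are constant
because the pipeline's filters are length-based. Truth labels ride in
FASTQ description fields so every stage is auditable.

What the simulator deliberately does not model: homopolymer/indel error
profiles of pyrosequencing, emulsion-PCR kinetics, chimeric/abortive
products, or quality-score structure. Passing round-trip tests therefore
demonstrates the correctness of the demux/trim/match/call logic under the
stated read geometry, not robustness to indel-rich instruments.

## Problem sizes and determinism

The default test and acceptance workloads are deliberately desk-scale:
the end-to-end round trip uses 3 loci × 20 alleles × 10 samples
(57,000 reads, a few seconds); oracle comparisons use 100 seeded
instances of 10-allele databases; novel-allele recovery uses 20 seeded
injections. All randomness flows through `numpy.random.default_rng`
seeded from a single integer, so every run, report and FASTA is
byte-reproducible from its configuration.

## Known limitations

* Real-run concordance figures (from patient/reference RNA on a 454 GS
  Junior) are not reproducible in silico and are out of scope; the
  acceptance layer substitutes property-based checks plus the printed
  coordinate arithmetic.
* The demultiplexer assumes FASTQ input with intact 5′ MIDs; flowgram
  (SFF) parsing is not implemented.
* Multiple alignments are consumed, not computed (use MAFFT/MUSCLE
  upstream for the design functions).
* Phasing across amplicons beyond shared-allele identity is not
  attempted; DRB copy-number (auxiliary DRB3/4/5 loci) is handled only
  insofar as calls carry their locus name.
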
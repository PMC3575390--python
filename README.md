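# csbt — cDNA sequence-based typing for HLA-style amplicon sequencing

`csbt` genotypes highly polymorphic immune loci (HLA class I A/B/C and
class II DRB) from multiplexed cDNA amplicon reads. It re-implements, as a
native Python library and CLI, a typing strategy built on three ideas:

1. **Pan-locus amplicons in a shared ORF frame.** Conserved primer sites
   found from a multiple alignment of all known alleles define two
   overlapping class I amplicons — HLA-1 (insert 50–725, 676 bp) and HLA-2
   (145–1069, 925 bp), together tiling nucleotides 50–1069 of the class I
   ORF — and one DRB amplicon (61–727, 667 bp). With per-end adapter+MID
   overhead (25 + 10 nt) the fusion products are 746, 995 and 737 bp, and
   the three amplicons are pooled 3:6:1 to equalise read yield.
2. **Exact-match mapping with typed match conditions.** Reference alleles
   are deposited with heterogeneous sequence extent (many are known only
   from exon 2 or exons 2/3). Each trimmed read group (1F/1R/2F/2R,
   DRB-F/DRB-R) is mapped at 100% identity at its expected offset, and
   every (allele, group) pair receives a condition: `1` (full match), `0`
   (perfect over the overlap, read extends past the known interval; a
   both-ends variant exists for exon-2-only DRB references), or `.` (no
   match possible because the reference lacks the region). Perfect
   key-group matches (2F for class I, forward for DRB) restrict the
   candidate allele set; inner/outer joins assemble a per-sample match
   matrix, and an allele is called when its observed row equals the row
   expected from interval geometry with sufficient reads per group.
3. **Typed failure modes instead of silent misses.** Name-distinct alleles
   identical over the region actually assayed are reported slash-joined
   (ambiguity sets); read-starved alleles can be rescued by a
   low-stringency mode with downgraded confidence; alleles supported by
   amplicon-1 reads but absent from the 2F key (e.g. a single-bp primer
   mismatch abolishing amplicon-2) are flagged `amplicon_discordant`;
   clustered unmatched reads within a few SNPs of a reference become
   putative novel alleles with per-SNP protein consequences.

The package also contains the companion design analysis (per-column
variability/depth profiles, conserved-window search, in-silico typing
resolution over any coverage region) and a synthetic read simulator that
generates allele databases, diploid genotypes, MID-tagged FASTQ reads and
truth tables, so the whole pipeline is testable without any external
database download.

## Worked example

Simulate a small run (4 samples, 3 loci) and type it:

```bash
csbt simulate --seed 7 --outdir demo --samples 4 --reads-per-amplicon 100
csbt run --config demo/pipeline.yaml
```

which prints the per-stage read accounting

```
simulated 7600 reads for 4 samples -> demo
24 genotype calls -> demo/typing/genotypes.tsv
  input: 7600
  length_rejected: 0
  mapped: 6517
  unassigned: 0
  unmatched: 1083
```

(the 1083 "unmatched" reads are real reads over regions the partial
references do not cover — e.g. 2R reads of an exon-2/3-only allele — and
feed novel-allele detection, which here finds nothing). The genotype table
`demo/typing/genotypes.tsv` begins

```
sample  locus  call        resolution  confidence   support
S01     A      A*01:05:01  6           unambiguous  2F=159;1F=74;1R=71;2R=0
S01     A      A*02:08     4           unambiguous  2F=145;1F=73;1R=82;2R=0
S01     B      B*01:03     4           unambiguous  2F=143;1F=69;1R=70;2R=161
...
```

Each row is one called allele (or slash-joined ambiguity set) with its
name-field resolution (4 = protein level, 6 = synonymous-variant level)
and per-read-group support; `2R=0` marks alleles whose reference is too
short to expect 2R matches. Against the simulator's truth table
(`demo/truth.tsv`) every genotype is recovered exactly.

The library surface mirrors the CLI: `simulate_run`, `demultiplex`,
`trim_filter`, `map_reads_exact`, `restrict_references`,
`build_match_matrix_classI/II`, `call_genotype`, `detect_novel`,
`in_silico_resolution`, all driven by a serializable `PipelineConfig`.

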
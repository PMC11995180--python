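# Methods

chimerakit post-processes chimeric-RNA (fusion transcript) candidate calls
from paired tumor/normal RNA-seq cohorts. It does not call fusions from raw
reads; it takes an EricScript-like candidate table plus a genome, a gene
annotation, per-sample FASTQ files and a clinical table, and produces a
classified, filtered catalog, per-sample junction-read support, long-read
validation calls and burden-based clinical associations. A synthetic cohort
generator with a machine-readable truth table makes every stage testable
end to end.

## Coordinate conventions

All internal coordinates are 0-based half-open. GTF (1-based closed) is
converted at the I/O boundary, so a write/read round trip is exact.
Candidate tables store 1-based breakpoint positions of the
junction-adjacent base (the last transcribed base of the 5' segment and the
first of the 3' segment), matching common caller output; they are converted
on read.

Gene models are gene-level: exons of all transcripts are merged into their
interval union, because the junction-site classification is defined per
gene, not per isoform. 3'UTR intervals come from `three_prime_utr` GTF
features; when absent they are derived as the exonic region transcription-
downstream of the CDS end, and genes with neither are marked
"undeterminable" (their candidates are retained and noted in the filter
report).

## Junction-site and genomic classification

Per candidate side, the breakpoint is **E** iff its transcription-oriented
junction edge coincides with an annotated exon boundary: the donor (5')
edge is one past the junction-adjacent base on `+` genes and the base
itself on `-` genes, mirrored for the acceptor (3') edge. Anything else —
mid-exon or intronic — is **M**; the two are not distinguished. An optional
±0–5 bp tolerance (default 0) absorbs caller imprecision.

Genomic class: **inter-chromosomal** iff the partner contigs differ;
otherwise **read-through** iff both genes are on one strand, the 5' gene is
transcriptionally upstream of the 3' gene, and the intergenic gap is
between 0 and `readthrough_max_gap` (default 100 kb — the literature calls
these cis-splicing products of *adjacent* genes but fixes no distance, so
the threshold is an explicit, configurable adjacency proxy); otherwise
**intra-chromosomal**. Overlapping same-strand gene pairs (negative gap)
are classified intra.

## Filter cascade

Stage order is fixed and logged: **M/M removal → cohort recurrence →
alignment uniqueness → 3'UTR flagging**. Order matters because the
recurrence tally is taken on the post-M/M catalog. Every stage emits a
report with `in = removed + surviving` checked at construction, and every
stage is idempotent.

* **M/M removal** drops the junction class with the lowest experimental
  validation rate.
* **Recurrence** keeps chimeras carried by ≥ `min_patients` (default 5)
  distinct patients; tumor and normal samples of one patient count once.
  Sample→patient mapping defaults to stripping a `_T`/`_N` suffix and is
  pluggable.
* **Alignment uniqueness** re-aligns each junction sequence to the genome
  with an internal seed-and-extend aligner (exact 11-mer seeds hashed over
  the genome, ungapped full-query placement per seed diagonal, identity
  scoring, both strands). A candidate is removed if the whole junction
  sequence is explainable by one contiguous genomic locus (identity ≥ 0.9
  over ≥ 90% of its length) — i.e. the "junction" is plain genomic
  sequence — or if either flank (half of the junction sequence) fails to
  align on the parental gene's contig at the same thresholds. This is a
  deliberate formalisation of re-alignment screening with BLAT-class
  tools, not a reimplementation of any specific tool's scoring; ungapped
  placement suffices because the question is only whether the query is
  contiguous genomic sequence.
* **3'UTR flagging** sets aside candidates whose 3' breakpoint falls in the
  3' gene's (annotated or CDS-derived) 3'UTR, a class with a high
  false-positive rate; flagged rows are excluded downstream but kept in
  the report.

## Junction-read quantification (approximate text search)

The short-read support of a chimera in a sample is the number of reads
containing the 2L-mer centred on the junction (L = 20 per flank by
default) within a Hamming mismatch budget k (default 2, capped at L/5).
Matching is the bit-parallel shift-and automaton (Baeza-Yates–Gonnet with
the Wu–Manber mismatch extension): state word `R_d` has bit j set iff the
length-(j+1) pattern prefix matches the text ending at the current
position with ≤ d mismatches. Patterns are limited to 64 nt so a state is
one machine word; the recurrence runs across all reads of a sample
simultaneously in numpy uint64 lanes. Reads are scanned on both strands
(the reverse-complemented pattern is also searched), each read counts at
most once per pattern regardless of occurrences, and N bases mismatch
everything — a conservative rule that keeps low-quality reads from
inflating support.

Differential support between tumor/normal pairs: counts are normalised to
counts-per-million of the sample's total reads (library sizes in the two
cohorts the method was built for differ mainly by sequencing depth), then
each chimera is tested with the paired Wilcoxon signed-rank across pairs
(zero differences dropped; all-zero ⇒ p = 1), with sign-test and paired-t
alternatives behind the same interface. Benjamini–Hochberg controls FDR
across chimeras; direction is the sign of the median paired CPM
difference. At least 6 complete pairs are required.

## Long-read validation (anchored, indel-tolerant search)

Long reads are searched for an extended junction pattern (2L', L' = 30 per
flank) under edit distance: semi-global alignment, pattern fully consumed,
read ends free. The dynamic program is the exact full-width recurrence,
vectorised one pattern row at a time; the horizontal (read-insertion)
dependency is closed-form resolved with a running prefix minimum
(`min_l≤j (tmp_l + j − l)`), so no banding or heuristic is involved. The
best placement is the leftmost minimal-distance end; its traceback prefers
matches, then deletions, then insertions.

A read supports a chimera iff (a) the best placement's distance is ≤
`max_edit_rate` × pattern length (default 0.1, i.e. 6 edits on 60 nt) and
(b) at least `min_flank_anchor` (default 20) pattern bases on **each**
side of the junction column are exactly matched in the traceback.
"Aligned" is operationalised as exactly matched — the strictest reading —
because both-flank anchoring is what rejects reads containing only one
parental gene, where the other half of the pattern merely drifts through
random sequence. Both strands are searched; support is the number of
distinct supporting reads, and a chimera/sample call is made at ≥
`min_reads` (default 1).

Sensitivity is defined at the **chimera level** (≥ 1 supporting read
anywhere), matching how long-read validation outcomes are counted in
practice. Per-read recall cannot be pushed to ~1 at these settings: with
8% per-base error the edit count in a 60-nt window is ≈ Binomial(60,
0.08), so ~18% of individual reads exceed a budget of 6; with several
spanning reads per carrier the chimera-level miss probability is
negligible.

## Burden and clinical associations

A patient's burden is the number of distinct surviving chimeras of one
genomic class (read-through by default) in the tumor sample. Patients are
split at the `split_quantile` (default 0.875) burden quantile — high group
strictly above, ties low, reproducing an 87.5%/12.5% stratification on
tie-free burdens — and compared with Kaplan–Meier curves and the 1-df
two-group log-rank test on biochemical-recurrence-free survival. Burden
across Gleason-score groups uses Kruskal–Wallis (midrank ties; the
all-identical degenerate case is reported as statistic 0, p 1) plus a
Gleason-6 vs ≥7 Mann–Whitney (no continuity correction, exact for small
tie-free samples). KM/log-rank come from lifelines and the rank tests from
scipy; the test suite pins the exact variants against hand-worked oracles
(an expected/observed log-rank table, exact Mann–Whitney enumeration,
the uncensored KM = empirical-survival identity).

Raw distinct-chimera count is the default burden; whether to normalise is
left as an explicit caller choice since stratification on raw counts is
the documented behaviour.

## Synthetic cohort generator

The generator emulates the data the analyses assume, not any real cohort:

* **Genome/annotation**: uniform-random ACGT contigs; genes laid along
  each contig without overlap, 3–6 exons of 150–300 nt, introns 200–400
  nt, intergenic gaps 300–600 nt; strands drawn with persistence 0.7 so
  same-strand neighbor pairs (read-through substrate) always exist; each
  gene gets a 60–120 nt 3'UTR at its transcription-terminal exon end and a
  complementary CDS, emitted as GTF features.
* **Chimeras**: per requested class combination, a partner pair is drawn
  from the eligible pool (same-strand neighbors for read-through;
  opposite-strand same-contig pairs for intra; cross-contig pairs for
  inter) and breakpoints are placed per class: E on a transcription-
  oriented exon edge, M strictly interior with a 55-nt margin from any
  edge (so planted labels can never collide with a boundary and junction
  flanks stay within one exon — a regularity real data does not promise).
  The chimeric transcript is the spliced 5' prefix joined to the spliced
  3' suffix. Optional 3'UTR-breakpoint chimeras place the 3' breakpoint
  inside the UTR; decoy candidates carry a verbatim contiguous genomic
  window as their "junction" sequence and wide recurrence, so they survive
  the early stages and must be caught by the uniqueness filter.
* **Reads**: single-end, uniform start positions, Poisson counts at the
  configured coverage; substitution-only errors for short reads,
  substitution+indel errors for long reads (matching the two matchers'
  error regimes); random strand. Chimeric junction reads are sampled at
  `tumor_normal_ratio` times the normal rate in a carrier's tumor sample;
  the ratio acts on the junction-read sampling rate so the differential
  signal is directly interpretable. Every read name carries provenance
  (`sample:serial|src=<transcript>|span=<0/1>`), so junction-spanning
  counts can be audited from names alone; with zero error and k = 0 the
  support matrix must equal this tally cell for cell.
* **Cohort**: biochemical-recurrence times are exponential with hazard
  h₀·exp(β·burden) (defaults h₀ = 0.01, β = log 3 — the effect size used
  for the power analysis), censoring is independent exponential with rate
  chosen so the baseline censoring fraction equals `censoring_rate`
  (default 0.3), and Gleason scores 6–10 are drawn from a categorical
  whose log-weights grow with burden (`gleason_enrichment` = 0.25),
  enriching high scores in high-burden patients.

The generator is deterministic byte-for-byte under its seed: each stage
draws from an independent child of one root SeedSequence. What it does
**not** emulate — quality-dependent or homopolymer error profiles,
fragment-length structure, paired ends, isoform diversity, expression
heterogeneity between genes, breakpoints near exon edges — bounds what
passing tests show about real data: they certify the algorithms'
contracts, not caller-level performance in the wild.

## Validation benchmarks and problem sizes

`chimerakit.benchmarks` (driven by `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures, per seed:

* matcher correctness: 1,000 randomized bitap cases (patterns 20–64 nt,
  k 0–3, reads with Ns) against a brute-force Hamming scan, and 500
  randomized embeddings (≤3 edits) against an unbanded quadratic DP;
* classification: 240 planted chimeras (20 per junction × genomic class),
  exact label agreement;
* filter cascade: a 10-patient cohort with 12 M/M chimeras, 5- and
  4-patient recurrence probes, 10 genomic-copy decoys and 3 UTR-breakpoint
  chimeras; exactness of every stage plus report conservation;
* quantification: 201 chimeras (one at 4× tumor/normal) across 30 pairs,
  error-free reads, k = 0; exact cell agreement, discovery of the planted
  chimera at BH q < 0.05, and the empirical false-discovery proportion
  among the 200 nulls;
* long-read validation: 24 chimeras, 8% read error, chimera-level
  sensitivity plus parental-only and swapped-flank decoy specificity;
* survival calibration: 1,000 null cohorts and 300 β = log 3 cohorts of
  n = 200 with Poisson(8) read-through burden — a mean granular enough
  that the 87.5% cut actually isolates a ≈12.5% high group, as in the
  stratification this reproduces (tie-heavy low-mean burdens degrade the
  split to ~5% and visibly inflate the small-sample chi-square);
* determinism: two full `run-all` executions compared byte for byte.

These sizes keep each benchmark's Monte-Carlo error well below the margins
being checked (e.g. SE ≈ 0.007 on the type-I rate at 1,000 cohorts).

## Numerical and degenerate-input choices

Ties in the burden split go to the low group. The log-rank statistic uses
no continuity correction. Wilcoxon drops zero differences; a chimera with
identical counts in every pair gets p = 1. Empty samples yield zero count
columns; an empty long-read file yields a logged zero-support result.
Transcripts shorter than the read length are skipped with a warning.
Reads containing N never match patterns at those positions. Candidate rows
referencing unknown genes, or joining a gene to itself, are dropped at
parse and counted. Provenance records contain the package version, a
config hash and input checksums but no timestamps, so identical seeds
give identical bytes.

## Known limitations

The uniqueness filter's flank check assumes junction flanks lie within one
exon (guaranteed by the generator, frequent but not universal in real
data); a flank spanning an internal splice junction could be falsely
removed, so the thresholds are exposed as flags. The genomic-class rule
cannot distinguish trans-splicing from rearrangement (both land in
intra/inter). Junction patterns longer than 64 nt are refused on the
bit-parallel path by design — the long-read (edit distance) path handles
them. The paired Wilcoxon treats counts as exchangeable within a pair and
ignores count overdispersion; the count-model alternative was deliberately
not added since junction-read counts per chimera are small and zero-heavy.
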
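# Methods

## Scope and data model

The toolkit starts from transcript models assembled elsewhere (e.g. a
Cufflinks-style GTF) and a protein-coding reference annotation
(GTF or gene→mRNA→exon GFF3). Internally all coordinates are 0-based
half-open; GTF/GFF3 I/O converts to and from 1-based inclusive. A
transcript is an ordered chain of non-overlapping exons on one strand;
introns are the gaps between consecutive exons, so spliced length plus
total intron length always equals the genomic span. Strand "." is
accepted for assembled transcripts (with a warning) but rejected for
the reference, because location classification is strand-aware.

A *locus* is a connected component of transcripts under same-strand
exonic overlap of ≥ 1 bp (transitive closure). This mirrors how
assemblers group isoforms operationally; transcripts whose spans
overlap only through introns stay in separate loci. The implementation
is a union-find over a start-sorted exon sweep; tests check it against
an O(n²) pairwise oracle and for input-order invariance.

## Filter cascade

Candidates must satisfy, in order: spliced length ≥ 200 nt and ≥ 2
exons; longest ORF < 300 nt; absence from five evidence lists
(protein hits, UTR fragments, coding-potential calls, Pfam domains,
structural ncRNAs). The per-step report telescopes; the final survivor
set is order-insensitive because each rule is a pure predicate.

**ORF definition.** An ORF is ATG-initiated and stop-terminated
(TAA/TAG/TGA), with the stop codon included in the length, scanned in
all six frames (the reverse strand via reverse complement). ORFs
truncated by the sequence end do not count, and codons containing N
match neither start nor stop — the most conservative deterministic
reading of an ORF-length threshold. A forward-strand-only mode is
available (`FilterConfig.orf_both_strands=False`) since ORF finders
differ on this point.

**Evidence as lists.** Homology and coding-potential evidence is
inherently external and database-version-dependent, so it enters as
transcript-ID lists produced by whoever ran the searches with their
thresholds (e.g. BLASTX e < 0.001, CPC ≤ −1). A reader for tabular
BLAST output (outfmt 6) with an e-value cut is provided. Evidence IDs
absent from the input are collected as "stale", not raised: lists
routinely outlive the assembly they were made from.

## Location classification

Seven classes; when several rules fire, precedence resolves them:
junction-shared > exonic sense > exonic antisense > intronic sense >
intronic antisense, with intergenic for no span overlap and
unclassified as residual. Junction sharing (an intron identical in
both coordinates) is the strongest structural evidence for a
relationship with the gene; exonic overlap beats intronic containment;
sense beats antisense. The overlap threshold is 1 bp — the smallest
unambiguous choice. Intronic antisense additionally requires *no*
exonic overlap with the gene, keeping it disjoint from exonic
antisense. The partner gene is the one achieving the winning class,
ties broken by largest exonic overlap then smallest gene_id, so
classification is a deterministic total function. A transcript on a
chromosome absent from the annotation classifies as intergenic with a
warning.

Unclassified covers strand-unknown transcripts over genes and genuine
rule gaps (e.g. a same-strand transcript whose exons sit in two
different introns without exonic overlap).

**Naming.** Intergenic loci are numbered densely in (chrom, start)
order as `<prefix>LINC<n>`; unclassified loci as `<prefix>LNC-unc<n>`;
partner-based names are `<gene>-IT` (intronic sense), `<gene>-AS`
(antisense — both exonic and intronic antisense share the suffix,
since "antisense" is the salient property), `<gene>-OT`
(sense-overlapping and junction-sharing). When several loci share a
partner gene and suffix the later ones get numeric suffixes (`-OT2`).
Within multi-isoform loci, members ordered by (start, transcript_id)
carry `-RA`, `-RB`, …; singleton loci omit the isoform suffix. Class
tables report per-class counts with percentages rounded half-up to two
decimals (so a printed table's percentages sum to 100.00 ± 0.02).

## Structural summaries

Exon-count histogram, mean/median spliced length, mean exon and intron
length, and the alternative-splicing fraction (share of loci with ≥ 2
isoforms). Exon and intron means are computed per element — every
exon/intron contributes once — because that is what "mean exon length"
usually denotes; a per-transcript mode (average within transcripts,
then across) is available since both conventions occur in the
literature. Length distributions are exported as binned counts, not
figures: binning is computation, plotting is presentation.

## Expression analysis

FPKM matrices are read from TSV; missing cells are imputed as 0 with a
logged count, negative values rejected.

**Specificity.** Row t is specific in sample s iff m[t,s] > 3 FPKM,
every other sample is < 1 FPKM, and m[t,s] ≥ 10 × the *maximum* of the
other samples (the stricter reading of "at least 10-fold higher than
those in other samples"; comparing to the mean is a config change).
With hi ≥ lo the rules force at most one specific sample per row.
The calls are scale-covariant: scaling the matrix and both FPKM
thresholds by c > 0 leaves them unchanged.

**Differential testing.** Welch's two-sample t-test per row on
log2(FPKM + 1) — the transform stabilizes variance and keeps zeros
finite — with Benjamini–Hochberg q-values over tested rows and calls
at p < 0.01 and q < 0.05. Degenerate rows (zero variance in both
groups) get p = 1 when the means agree and p = 0 otherwise. Designs
without replicates get fold-change ranking only, with a warning:
producing p-values from n = 1 would be fabrication.

**Clustering.** Average-linkage (UPGMA) agglomeration on
1 − Pearson r between rows; rows are sorted by id first so
tie-breaking is deterministic and the output is invariant to input row
order up to relabeling. Constant rows have undefined correlation; r is
taken as 0 (distance 1) with a log message.

## Neighbor co-expression

The nearest gene minimizes span-to-span gap on the same chromosome,
strand ignored (an antisense neighbor is still a neighbor); overlap
means gap 0. Distance bins are half-open: overlap, 0 < d < 5 kb,
5 kb ≤ d < 10 kb, d ≥ 10 kb — so a gap of exactly 5 kb falls in the
second bin. Ties go to the smallest gene_id; a chromosome without
genes yields infinite distance, flagged.

The co-expression test compares Pearson r over neighbor pairs with r
over `n_random` uniformly drawn (lncRNA, non-neighbor gene) pairs
(fixed seed, with replacement; true neighbor pairs and caller-supplied
exclusions are never drawn), using a Welch t-test between the two r
distributions. Pairs missing from the matrix or with constant profiles
are dropped and counted. |r| > 0.8 marks strong pairs. Because null
pairs reuse rows, their correlations are not fully independent; with a
null sample size commensurate with the pools (defaults: 40 neighbor
pairs, ~240 genes, 200 null draws) the test's type-I error is close to
nominal (measured ≈ 0.045–0.05 at α = 0.05 in the calibration suite).

## Synthetic fixtures

The generator emulates the statistical profile of an insect lncRNA
catalog: lncRNAs mostly two-exon with long exons (~363 bp mean,
lognormal) and long introns (~7.8 kb), protein-coding genes with more
but shorter exons (~250 bp) and ~2.6 kb introns; 12 expression samples
with lognormal between-sample noise. Class-planted transcripts are
constructed geometrically against dedicated host genes (inside an
intron, overlapping an exon, sharing an intron exactly, strand-flipped
variants, strand-unknown for unclassified), so the intended class is
true by construction and the classifier must recover 100 % of labels.

Two devices make planted truth exact rather than probabilistic:

* **ORF-free background.** Genome sequence is drawn uniformly over
  ACGT and then scrubbed of every `ATG` and `CAT` substring (the
  latter is the reverse-strand start), so no complete ORF exists
  anywhere except planted cassettes; splice-junction concatenations of
  every emitted transcript are scrubbed the same way. Cassettes are
  `ATG` + T-free interior codons + `TAA`: T-free codons can encode
  neither start nor stop in any frame on either strand, so the planted
  ORF length (default 402 nt — an ORF is necessarily a codon multiple)
  is exact, and the generator verifies every transcript's longest ORF
  against its intended value before returning.
* **Rejection sampling of expression rows.** Background rows that
  accidentally satisfy the specificity rule are redrawn, so the
  planted specific set is the exact truth set.

Neighbor co-expression is planted on a latent bivariate-normal scale:
the gene's per-sample z-scores and the lncRNA's are correlated at ρ
(default 0.5) before lognormal exponentiation, which attenuates the
realized FPKM-scale Pearson r to ≈ 0.44 at 12 samples.

The differential fixture plants 8-fold shifts in 50 of 2000 rows with
3 + 3 replicates and lognormal replicate noise σ = 0.08 (log scale,
~8 % CV — low-dispersion technical replicates). The noise level is a
deliberate power calibration: with three replicates the Welch degrees
of freedom are ~2–4, and the planted shift stops being reliably
detectable at BH-corrected cutoffs once replicate CV grows past ~15 %,
which would make the fixture's "differentially expressed" labels false
as ground truth. At these settings the suite measures type-I error
≈ 0.006 at p < 0.01 and recall ≈ 0.97.

What passing these tests shows — and does not. The fixtures exercise
coordinate arithmetic, rule logic, orderings and calibration exactly,
but real data differ: assembled transcripts have fragmentary and
misassembled models, expression noise is overdispersed and correlated
across samples, coding genes contain real ORFs, and evidence lists are
noisy. Truth recovery on fixtures validates the machinery, not the
biological error rates of a real catalog.

## Problem sizes and numerical choices

The default fixture is 2 chromosomes (~1.4 Mb each, sized
automatically to fit the layout), 220 coding genes and 30 planted
lncRNAs per class; the acceptance script runs this plus 20 seeds of
the 2000-row differential simulation and 300 seeds of the
co-expression simulation, all in well under a minute. Percentages are
rounded half-up (decimal arithmetic, not binary floats); Pearson r
requires ≥ 3 observations and non-constant vectors, erroring
otherwise; BH q-values come from the standard step-up procedure and
are monotone in p-rank. Seeds are mandatory everywhere randomness
exists; the same seed reproduces every output byte-for-byte.

## Known limitations

* The locus definition (same-strand exonic overlap) is one of several
  in use; single-exon antisense fragments can split loci that a
  span-based definition would merge.
* Classification precedence is a modeling choice; a transcript that is
  both exonic-antisense to one gene and intronic-sense to another
  reports only the higher-precedence class (the order is
  configurable).
* The UTR-fragment filter step has no reproducible algorithmic
  definition and is honored only through evidence lists.
* The co-expression null reuses expression rows across random pairs;
  its t-test is approximate, and calibration degrades if the null
  sample size greatly exceeds the information in the pools.
* Welch testing with three replicates has little power for shifts
  under ~4-fold at realistic noise; the toolkit reports honest
  p-values rather than moderated ones.
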
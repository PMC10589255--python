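# Methods

`paraquant` quantifies the expression of individual members of a young
tandem gene family — gene copies so similar (~99% nucleotide identity)
that conventional read mapping cannot assign reads to a specific paralog —
and tests how copy number, paralog identity, and cell type shape that
expression. The motivating system is a testis-expressed, X-linked tandem
array in *Drosophila melanogaster* with 3–6 copies per strain, but every
component is generic over any panel of near-identical co-linear paralogs.

## Diagnostic motif model

Read assignment is alignment-free and rests on *diagnostic sites*:
positions at which one paralog's base differs from every other paralog's
base in the strain. Each paralog receives a two-part motif:

* a **core** of 20 nt containing a diagnostic site, required to occur
  exactly once in the target (both strands) and never in any non-target
  paralog or parental/decoy sequence;
* an **extended** motif of 130 nt — the core plus 55-nt flanks taken from
  the target sequence.

A read counts toward a target iff the read or its reverse complement
contains the core verbatim and, anchoring the extended motif at that core
occurrence, at most one position mismatches over the read/extended
overlap. Reads (100 nt) are shorter than the extended motif, so mismatches
are counted over the overlap only; the perfect-core requirement is
absolute. 'N' counts as a mismatch; multiple core occurrences are each
tried.

A family-wide "ALL" motif is drawn from the first-exon segment shared by
all paralogs and absent from the parental genes, measuring total family
expression with the same machinery.

Design guarantees are made checkable. Candidate cores are centred on
diagnostic sites; among candidates passing the uniqueness checks the
design maximises the minimum Hamming distance from the extended motif to
every equal-length window of every non-target sequence on both strands
(ties: leftmost), and requires that minimum to be at least
`min_cross_distance = 2`. With distance ≥ 2, an error-free read from a
non-target can never pass the one-mismatch screen — the specificity
property the test suite asserts exactly. `verify_uniqueness` recomputes
both guarantees by exhaustive scan and returns a per-motif certificate;
design output always passes its own certificates. For a single-copy
family every window is trivially unique and the leftmost qualifying
window is taken.

Paralogs are assumed co-linear: diagnostic sites are read off equal-length
sequences (or a user-supplied gapless alignment; gap or N columns are
never diagnostic). At ~99% identity indels are rare enough that alignment
handling would add complexity without changing the motifs. Coordinates
are 0-based, half-open, on the sense strand. An optional per-paralog
exclusion-zone parameter keeps motifs away from regions the user
distrusts (e.g. transcript ends subject to exosome degradation); it is
off by default because that is a biological judgement, not an algorithmic
one.

## Quantification

Counts are normalised as RPKM against the total number of reads in the
FASTQ input — not reads mapped to a genome, since no genome mapping is
performed — and the fixed motif length:

    RPKM = count / ((motif_length / 1e3) · (total_reads / 1e6))

with motif_length = 130 for all motifs, making the length term a common
constant. Paired mates are screened as independent reads and both count
toward `total_reads`. Both strands are scanned regardless of library
strandedness; this is conservative and orientation-agnostic (the original
libraries are stranded, but orientation handling is not documented, so
the screen must not depend on it). A (strain, target) is flagged
*reliable* only when the raw count is ≥ 10 in every replicate; unreliable
entries are kept in the output but excluded from statistics.

## Bulk statistics

Expression values are log10-transformed (reliability guarantees
positivity). One-way ANOVA tests differences among strains or among a
strain's paralogs; Levene (median-centred) and Shapiro–Wilk (on pooled
residuals) p-values are reported alongside but never switch the
procedure — no nonparametric fallback is defined, so gating would silently
change the analysis. Significant ANOVAs get Tukey–Kramer HSD post-hocs
(unequal-n form, α = 0.05, stars at 0.05/0.01/0.001). The copy-number
regression is ordinary least squares of log10 total-family RPKM on copy
number using replicate-level points (3 per strain, 12 for four strains)
rather than strain means: the replicate scatter is real measurement
variation and the reported degrees of freedom match the replicate count.
Pairwise expression-profile correlations use Pearson's r with
Benjamini–Hochberg adjustment; BH is used wherever a multiple-test
correction is needed but no method is forced by context.

## Equal-partitioning test

The null of interest is that each of k paralogs contributes 1/k of total
family expression, making the k·m replicate RPKM values exchangeable
across paralog slots. Each permutation pools all values and reassigns
them, m per slot; per paralog,

    p_high = (1 + #{permuted slot mean ≥ observed mean}) / (n_perm + 1)

and p_low analogously, with add-one smoothing so no p is ever zero
(minimum attainable p = 1/(n_perm+1)). Both one-sided tests for all k
paralogs (2k tests) are BH-adjusted within the strain; calls are
"higher"/"lower" at adjusted p < 0.05, else "consistent". Because ties
count toward both sides, p_high + p_low ≥ 1 + 1/(n_perm+1) always, so a
paralog can never be called both higher and lower at α ≤ 0.5. Pooled
value reassignment is the weakest exchangeability assumption consistent
with "even contribution"; replicate linkage is deliberately not
preserved. The test runs on the RPKM scale, not log, because it concerns
contribution shares. An exhaustive mode enumerates all C(k·m, m) subsets
of the pool as candidate slots and reports exact unsmoothed
probabilities; it pins down the test's definition at small k·m (k=2, m=3
has 20 assignments) and serves as the oracle for the Monte Carlo path.
Default n_perm = 10,000; the seed is a required parameter.

## Single-cell layer

Clustering, doublet removal and cluster annotation are inputs (a
barcode → cell-type table), never computed. QC keeps genes detected in
≥ 3 cells and then cells with 200–8000 detected genes, both bounds
inclusive, gene filter first and not iterated (the order is otherwise
ambiguous). Marker testing is a two-sided Wilcoxon rank-sum of each
(gene, type) against all other cells, BH-adjusted across every (gene,
type) test; a type is flagged when adjusted p < 0.05 and its mean exceeds
the rest-mean, and the flagged type with the highest mean is the gene's
peak. Percent-expressing is the fraction of a type's cells with count
> 0 (no detection threshold). The family aggregate is a pseudo-gene
summing member counts per cell before normalisation, flowing through the
same summaries.

The built-in normalisation for marker input is log1p of counts-per-10k —
a deliberately simple library-size stand-in; externally normalised
matrices (e.g. variance-stabilised) are accepted and preferred. The
read-level route extracts a 16-nt barcode from R1 (UMI parsed but not
deduplicated — the quantity of interest is reads), screens R2 with the
motif catalog, discards and tallies unannotated barcodes, and reports
per-type RPKM with the type's assigned read count as denominator so that
small cell types remain comparable; a whole-library denominator is
available behind a flag since neither convention is forced.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, with
ground truth recorded throughout:

* **Panels** — paralogs are copies of one 5,000-nt uniform-random
  template; the first 300 nt are the shared "first exon" (substitution-
  free, absent from the independent 3,000-nt random decoy standing in for
  the parental genes). Each paralog's `divergence_sites` substitutions
  (default 5) land at disjoint positions inside a ~110-nt cluster within
  a paralog-private block, which guarantees (a) every substituted
  position is a diagnostic site and (b) some 130-nt window holds ≥ 2 of
  them — the designability condition for cross-distance 2. Disjoint
  placement makes pairwise Hamming distance exactly d_i + d_j, so
  pairwise identity stays ≥ 99% on the 5,000-nt template whenever
  d ≤ 25.
* **Bulk libraries** — fragments are multinomial across paralogs plus a
  decoy background (shares sum to 1 exactly, so truth counts plus
  background equal the library size exactly); inserts are uniform on
  [read length, 300] nt with uniform starts; the dUTP convention (mate 1
  antisense, mate 2 sense) is the default with an "fr" switch, since the
  library dialect is not documented; errors are i.i.d. per-base
  substitutions; qualities are constant placeholders (quality handling
  belongs upstream). Default design: four strains with copy numbers
  3/4/5/6, three replicates, 100-nt paired reads, error rate 0.001
  (typical modern substitution error), family share proportional to copy
  number (equal per-copy output).
* **Cells** — cell types with given proportions and per-gene mean reads;
  per-cell counts are Poisson; R1 is barcode(+UMI), R2 a sense cDNA read;
  the written matrix equals the realised counts exactly. Barcodes are
  generated unique by construction; duplicate barcodes in a user
  annotation raise.

All outputs are byte-identical under a fixed seed. Not emulated: indels,
PCR duplicates, UMI collisions, realistic quality profiles, gene
conversion between paralogs, positional coverage bias. Passing tests
therefore demonstrate correctness of counting and inference under the
stated generative model, not robustness to alignment artefacts or
library-prep biases in real data.

## Numerical and scale choices

* Identical ANOVA groups (no variance anywhere) are reported as F = 0,
  p = 1; a constant regression response returns slope 0, R² 0, p 1;
  constant copy number raises (slope undefined). Zero-variance profiles
  yield missing correlations rather than errors.
* The acceptance run (`scripts/acceptance.py`) uses 250,000 fragments
  (500,000 reads) per replicate across 12 libraries, 10,000 permutations
  per strain, and 400 cells — sizes at which every reported quantity is
  stable under the seed while the whole run stays around a minute. The
  copy-number recovery experiment in the test suite runs at the
  expression-matrix level (log-normal replicate noise, log10 SD 0.08 ≈
  20% CV, a realistic replicate scatter for pooled-tissue RNA-seq)
  because 200 full read-level repeats would add nothing to what the
  read-level proportion-recovery test already establishes.
* Hypothesis-based property tests are derandomised; all stochastic tests
  fix their seeds.

## Known limitations

* Co-linearity is assumed; a paralog with a large internal indel needs a
  user-supplied gapless alignment (gap columns are simply ignored).
* The two-stage screen is conservative: reads overlapping less than the
  full core, or family reads with two sequencing errors inside the
  window, are missed. RPKM against motif length corrects scale but
  motif-local coverage biases (e.g. a motif near a transcript end) remain.
* The partition test assumes replicate values are exchangeable under the
  null; strong replicate (batch) effects would violate this and inflate
  calls.
* Per-type RPKM with per-type denominators is not comparable with
  whole-library RPKM; pick one convention per analysis.
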
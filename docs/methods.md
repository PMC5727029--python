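# Methods

This note documents the models, defaults, and numerical choices behind
`apakit`, and what the synthetic data does and does not emulate.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
BED (0-based half-open) convert at the I/O boundary, which keeps every
off-by-one in one place. Isoforms of a gene are merged: exons are the
interval union across isoforms, introns are the gaps between merged exons
(i.e. regions exonic in *no* isoform), and the 3′-most exon is the most
distal merged block among the isoforms' last exons (every merged last-exon
block counts as 3′UTR territory during classification). The merged-gap
intron rule is slightly stricter than requiring only "intronic in at least
one isoform", but it is deterministic, symmetric in the isoforms, and
identical on single-isoform annotation, which is what the generator emits.

Intron ordinals are assigned in transcription order with first/last taking
precedence over second/second-to-last: `+1`, `-1`, then `+2`, `-2`, then
`MIDDLE`. Genes with four introns therefore use `{+1, +2, -2, -1}` with an
empty middle group.

A PAS up to `utr3_extension` (default 1000 nt) downstream of the 3′-most
exon is classified UTR3 — 3′-end reads routinely map just past the
annotated end. This is an assumption, not something the data formats
encode; a gene whose annotated body contains the position always beats a
neighbour that reaches it only through this extension.

## PAS discovery

A read supports a cleavage event when its tail-side soft clip, read in
transcript orientation, is a strict run of poly(A) bases (A at the genomic
right end of a plus-strand transcript; T at the left end of a minus-strand
one) of which at least `min_unaligned_t = 2` do not match the genome
beyond the alignment. The templated-ness check is what separates a real
poly(A) tail from a read that merely stops in front of a genomic A run.
The cleavage position is the last aligned base in transcript orientation.

Cleavage positions within `max_gap = 24` nt are merged by single-linkage
chaining. On a line this reduces to splitting sorted positions at gaps
larger than the threshold, which is order-independent and idempotent; the
test suite checks it against an O(n²) repeated-merge oracle. The cluster
representative is the position with the most reads, ties broken toward the
transcript-3′ (distal) side — the dominant cleavage site is the stable,
biologically meaningful summary.

Internal priming is filtered by sequence: a cluster whose downstream 10-nt
window (transcript orientation) contains ≥ 6 adenosines is discarded.
Bases beyond the contig end count as non-A. The filter defaults to on for
the read path and is skipped on the count-table fast path, whose inputs
are assumed pre-filtered.

## Poly(A) signal

The A[A/U]UAAA signal is searched in the −40..−1 window upstream of the
cleavage site (transcript sense, T ≡ U, reverse-complemented on minus
strands) with priority AAUAAA > AUUAAA > close variants > none. The
variant set defaults to the ten single-nucleotide substitutions of AAUAAA
used in poly(A)-signal surveys (AGUAAA, UAUAAA, CAUAAA, GAUAAA, AAUAUA,
AAUACA, AAUAGA, AAUGAA, ACUAAA, AAGAAA) and is configurable. Within a
priority tier the occurrence nearest the cleavage site wins — proximity is
the dominant signal when a window contains several candidates.

## Differential APA

Per gene, the two most abundant 3′UTR PASs (reads summed over all samples;
second-slot ties broken distal) form the proximal/distal pair. With
replicate-pooled counts per condition and pseudocount 0.5,

* RE = log2((distal + 0.5)/(proximal + 0.5)) per condition,
* RED = RE(treated) − RE(control),
* Δ relative abundance = distal fraction (raw counts) treated − control.

Intronic APA substitutes the pooled intronic-PAS set for "proximal" and
the pooled 3′UTR-PAS set for "distal", so activation appears as a negative
Δ of the 3′UTR set, mirroring shortening.

The significance test is a two-sided Fisher's exact test on the 2×2
replicate-pooled isoform × condition table, plus a sign-consistency
requirement: a strict majority of replicate pairs (paired by replicate
number) must shift the distal fraction in the pooled direction. This is a
deliberate, documented substitute for a negative-binomial GLM with
dispersion shrinkage (DEXSeq-style): it is exact, dependency-free, and on
replicate-pooled counts slightly anti-conservative under biological
overdispersion — the sign-consistency majority is the cheap guard against
being driven by a single replicate. Calls additionally require
|Δ relative abundance| > `min_delta = 0.05`, read as 5 *percentage points*
(absolute fraction), the standard usage in this literature. Per the
field's convention, APA calls use the unadjusted p < 0.05 while gene-level
differential expression uses BH FDR. Genes below `min_gene_reads = 20`
summed over samples and tested isoform sets are excluded: fraction
estimates below that are noise.

Supporting statistics:

* **Weighted 3′UTR length** — per condition, isoform lengths averaged with
  read weights over *all* 3′UTR isoforms of the gene. Lengths are measured
  as the transcript-orientation offset of each PAS within the 3′-most
  exon; only within-gene differences are ever interpreted, so the choice
  of origin (exon start rather than stop codon) cancels.
* **aUTR bins** — genes ranked by aUTR size (distal − proximal distance)
  into `n_bins = 5` equal-count quantile bins; mean RED ± SEM per bin, and
  a two-sided Wilcoxon rank-sum between the extreme bins.
* **Intron-position profile** — intronic PAS isoforms of genes with ≥ 4
  introns and ≥ 2 supporting reads, grouped by intron ordinal. Per isoform
  the log2 treated/control ratio of library-size-normalised mean counts
  (median-of-ratios size factors computed on gene totals — ratio
  statistics need between-sample scaling); group means are mean-centred by
  subtracting the mean of the group means; Wilcoxon rank-sum compares the
  first- and last-intron groups. Mean-centring shifts all values by a
  constant and does not affect the test.

## Differential expression and coupling

Expression uses only CDS-overlapping reads (≥ 1 bp overlap, strand-aware,
primary alignments only; reads touching the CDS of two genes are
discarded), so 3′UTR changes cannot contaminate the gene-level signal.
Counts are normalised by median-of-ratios size factors (note these are
identified only up to a common scale). The per-gene test is a two-sided
moderated t on log2(normalised count + 1): the pooled within-group
variance is shrunk toward the across-gene median with `prior_df = 10`
pseudo-degrees of freedom, and the t reference uses the combined degrees
of freedom. A plain per-gene Welch t at three replicates has four residual
degrees of freedom and essentially no BH-significant calls at realistic
fold changes; sharing variance information across genes is the standard
remedy and the closest self-contained analogue of the dispersion shrinkage
that count-model packages perform. UP/DOWN requires BH FDR < 0.1 and fold
change > 1.2.

Coupling analyses group the expression log2 ratios by APA class
(boxplot-style summaries plus pairwise Wilcoxon tests), and
`platform_correlation` gives the Pearson r of per-gene condition ratios
between two independent count sources. `region_restricted_ratio` computes
condition ratios separately for the gene regions up- and downstream of an
intronic PAS — the single-gene diagnostic for expression loss confined to
exons beyond a truncation site.

## Consequence annotation

Removal is interval logic in genomic coordinates, not transcript
re-splicing: a miRNA site of a gene called SHORTENED is REMOVED iff it
lies strictly between the proximal and distal PAS; a domain of a gene with
ACTIVATED intronic APA is REMOVED when entirely downstream (transcript
orientation) of the dominant intronic PAS, TRUNCATED when spanning it,
RETAINED otherwise. Because the literature counts "removed or truncated"
both ways, the domain tallies report REMOVED and TRUNCATED separately and
the gene-level tally treats either as affected.

## Synthetic data

The generator emulates the statistical structure this pipeline consumes:
multi-exon genes (default 4–7 introns, so every gene is eligible for the
position profile) on both strands of a toy genome; two (configurable) 3′UTR
PASs with log-uniform aUTR sizes plus an intronic PAS in half the genes;
per-condition usage fractions with programmed shortening / lengthening /
intronic-activation shifts (default Δ = 0.3 in fraction points, 3
replicates per condition, mean depth 500 reads per gene, NB dispersion
0.1 — dispersion 0 degrades to Poisson); lognormal gene-abundance
variation; independent gene-level expression multipliers; hexamers planted
in the −40..−1 windows at 55% AAUAAA / 17% AUUAAA / 20% other variant / 8%
none (windows for the "none" class are scrubbed of adenosines so no signal
can occur by chance); and simulated reads whose untemplated-A tail length
is 2 + Poisson(1), i.e. every emitted read carries a detectable tail,
with configurable cleavage jitter (default ±10 nt, inside the 24-nt
clustering radius) and internal-priming decoy reads that end just upstream
of planted A₁₀ tracts with a partially templated tail — they survive tail
extraction and are removed by the A-rich filter, which is exactly the
pathway the filter exists for.

What it does not emulate: sequencing error, adapter artefacts, mappability,
isoform-fraction overdispersion across replicates (usage fractions are
fixed per condition; only gene totals are overdispersed), correlated
genes, or annotation error. Passing recovery tests on this generator
therefore demonstrates correctness of the statistical machinery under its
stated model, not robustness to the full messiness of real libraries.

## Determinism and problem sizes

All randomness flows from a single integer seed per generator or simulator
call (NumPy `default_rng`); identical arguments reproduce byte-identical
outputs, and the truth table is the same whether or not genome sequence is
materialised. The test-suite and acceptance-script problem sizes (200–1000
genes, depth 300–500, 3 replicates, 40 repeated seeds for the uncoupling
property) were chosen as the smallest sizes at which the tested properties
are statistically stable; each acceptance analysis states its size in its
output.

## Known limitations

* The Fisher + sign-consistency test ignores within-condition biological
  variability of isoform *fractions*; with strongly overdispersed usage it
  will be anti-conservative relative to a GLM with per-gene dispersion.
* Proximal/distal selection pools counts across conditions (deciding
  between the unstated alternatives); a PAS dominant in only one condition
  can displace the pair.
* The detection rule behind the census ("≥ 2 reads in ≥ 1 sample of the
  condition") and the exact construction of the region-fraction binomial
  test (condition A's intronic count against condition B's fraction) are
  reasonable choices among several the input data cannot distinguish.
* CDS counting uses primary alignments only and drops multi-gene reads;
  no fractional assignment.
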
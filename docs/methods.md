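# Methods

This note documents the statistical models, the synthetic-data
generator, numerical choices, and the design decisions taken where the
design was genuinely open. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All internal coordinates are 0-based half-open; GFF (1-based inclusive)
and wiggle (1-based) conversions happen only at the I/O boundary in the
annotation module. Bulk read sets are pandas DataFrames (one row per
uniquely mapped read, with a junction flag and intron span); genes are
immutable `GeneModel` records with gene body, CDS and derived introns.

## Strand-specificity background

A strand-specific library assigns each read to the wrong strand with
some small probability *e*. Junction reads expose *e* directly: a read
whose gap matches an annotated intron has a known true orientation, so
*p̂*<sub>bg</sub> = wrong / matched, with an exact Clopper–Pearson 95%
CI. The rate is estimated **per library**, not pooled. Junction reads
matching no annotated intron are excluded. If a library yields zero
wrong junction reads, the pipeline substitutes half the CI upper bound
as a conservative nonzero background rather than testing against 0.

## Antisense calling

Per gene and condition, replicate counts are summed and the antisense
count *a* is tested against the null that all antisense reads are
strand-assignment artifacts:

* default null: X ~ Binomial(*n*, *p*<sub>bg</sub>), *p* = P(X ≥ *a*),
  computed with the regularized-incomplete-beta tail (verified against a
  50-digit direct cumulative summation to better than 1e-12 relative
  error for n ≤ 10⁴ in the acceptance suite);
* optional negative-binomial null with mean *n·p*<sub>bg</sub> and a
  dispersion either supplied or estimated by method of moments from
  genes in the bottom expression decile (where antisense should be pure
  background). The estimate is used only when positive; as dispersion →
  0 the NB tail converges to the Poisson/binomial tail.

When per-library background rates differ, the pooled null uses the
read-count-weighted mean rate — an approximation to the exact
sum-of-binomials null that is indistinguishable at the ~0.1-percentage-
point rate differences junction QC produces.

Multiple testing is Benjamini–Hochberg per condition ("q value"); a
gene *has antisense expression* if called in either condition at
q < 0.01. On generator data the empirical FDR is ≤ 2% and sensitivity
is ≥ 90% for loci whose expected pooled antisense count is ≥ 25
(acceptance suite: 10 seeds at 5000 genes × 2 × 10⁶ reads/library).

**Dominance.** Antisense is dominant in a condition iff
antisense_level ≥ sense_level on normalized levels (ties dominant).
The two-condition category letters (PP/PN/NP/NN) use 'P' when
sense ≥ antisense; at an exact tie a gene is both "dominant" and
lettered 'P' — the two conventions are deliberately kept as stated and
only disagree on ties.

## Normalization

level = count / (effective length in kb × library total in millions).
The sense expressed region is exonic; the antisense expressed region is
the **full gene span including introns** (the antisense transcript has
its own, unknown, intron structure), so the two strands of one locus
have different effective lengths. Both are scaled by the gene's
mappable fraction when a mappability track is supplied; mappability
counts k-mer occurrences over both genome strands, and
reverse-complement-palindromic k-mers are therefore never unique
(documented edge rule). Zero effective length yields a flagged NaN
level, never 0.

## Counting rules

A read counts for a gene when ≥ 1 bp of its exonic footprint (junction
reads contribute their two segments) intersects the gene body. Reads
hitting both genes of an annotated 5'–5' or 3'–3' overlapping
coding-gene pair are discarded as ambiguous; a read overlapping two
non-overlapping genes is assigned to the gene containing its 5' end.
Sense-strand reads wholly inside the gene's intron are not counted
(sense region is exonic); antisense counts over the full span. Every
read lands in exactly one of {sense, antisense, ambiguous, unassigned}
— the per-library accounting is exact, and counting is invariant under
read order.

## Differential expression (SAM-style)

Per gene, d = (mean<sub>HS</sub> − mean<sub>NM</sub>) / (pooled SE + s₀)
on log2 levels with a 0.5 pseudocount; s₀ defaults to the median pooled
SE. The null is built from condition-label permutations — exhaustive
when ≤ 500 distinct assignments (C(4,2)=6 for 2v2, C(8,4)=70 for 4v4),
seeded sampling otherwise. The reported permutation p is one-sided in
the fixed HS > NM direction (exactly uniform on {1/B, …, 1} under label
exchangeability, minimum 1/6 for 2v2); a doubled two-sided companion
column is included. Significance is decided by q — for each |d|
threshold, the median across permutations of the genome-wide count of
|d*| above it, over the observed count, clipped to [0,1] and made
monotone — together with the fold criterion (>2 or <0.5 on linear
levels). Technical replicates are treated as additional libraries, so a
2-bio + 2-tech design permutes as 4v4.

**Coordination classes.** Both strands significant and same direction →
correlated; opposite → anti-correlated; only antisense → independent_AS;
only sense → independent_S; neither → unchanged. The five classes
partition all genes tested on both strands.

## Gene-pair mechanism tests

Correlations are computed **across libraries** (conditions ×
replicates) per pair on log2 levels with a pseudocount — the only
version that tests a shared production mechanism — and pooled across
pairs on the Fisher-z scale. For tandem pairs, the focal
(antisense-carrying) gene is the upstream one — the left gene of a
(+,+) pair, the right of a (−,−) pair — and the predicted correlate is
the downstream neighbour's sense level; the pooled test is a paired
Wilcoxon signed-rank of z(r_partner) vs z(r_own). For convergent pairs,
either gene can be the read-through recipient; analysis restricts to a
supplied focal set (e.g. antisense-called loci) or analyzes both
directions, and the pooled test asks whether z(r_partner) is centered
above 0. Pairs with constant levels (zero variance) are skipped and
logged, never given r = 0.

With 8 libraries per pair, a per-pair r is noisy (Fisher-z sd ≈ 0.45);
recovery of a planted coupling to ±0.1 therefore uses the z-pooled mean
over 100 pairs, and the correlation-recovery experiments disable
differential expression so that the across-library correlation reflects
the coupling alone (condition effects shared through a coupled promoter
would otherwise add a common component and push r above ρ).

## Occupancy metaprofiles

Probes are normalized to log2(IP/WCE), mapped into a strand-oriented
gene frame (negative = upstream of the ORF start of the sense
transcript), and smoothed per gene with a Nadaraya–Watson Gaussian
kernel, sd 40 bp — a convex combination, so smoothed values stay within
the data range; grid points whose total kernel weight underflows are
NaN and excluded from group means. In the composite ORF frame the two
1 kb flanks stay in bp while the gene body is scaled to 100 bins, making
genes of different lengths comparable; single-anchor frames (ORF start
/ ORF end ± 1 kb) stay in bp. The profile reports the per-position mean
and SD **across genes**. Genes with CDS < 200 bp are excluded.

Stratification emits sense-level tertiles (ties broken by gene id), an
AS/S median split within the low tertile, and expression-matched
called/uncalled groups built by stratified subsampling over 20 rank
bins of sense level; matching must pass a two-sided rank test of
sense-level equality (p > 0.1) or it raises. Group comparisons are
one-sided Wilcoxon rank-sum on per-gene mean log2(IP/WCE) over a stated
region (body or flank); identical or overlapping groups are an error.

## Synthetic-data generator

The generator emulates the study design end to end: two conditions
(NM/HS) × ≥2 replicate libraries of 36-nt stranded reads, gene bodies
with one central 100-bp intron (junction QC support; simulated
antisense transcripts carry no introns), tandem/convergent/divergent
neighbourhoods, and tiling occupancy probes with IP and WCE channels.

* **Layout.** Genes are placed in two-gene blocks with within-block
  gaps below the 1 kb pairing cutoff and between-block gaps above it,
  block orientation i.i.d. from `orientation_fractions`. A single chain
  of abutting genes cannot realize arbitrary convergent/divergent
  fractions (strand flips alternate between the two), so block placement
  is what makes the orientation mix exactly multinomial. An optional
  fraction of convergent/divergent blocks overlaps by 20–80 bp to
  exercise ambiguous-read removal.
* **Rates.** Per-gene sense rates are log-normal (log-sd 1.0 by
  default); 15% of genes are differentially expressed 4-fold between
  conditions, in each direction. A fraction (default 0.4) of genes
  carries true antisense transcription: `own_promoter` loci draw an
  antisense rate of 5–50× the strand-error background of their own
  sense rate (a 15% slice instead draws 1–5× the sense rate itself,
  modelling antisense-dominant loci, ~5% of genes);
  `bidirectional_promoter` (tandem focal) and `read_through`
  (convergent focal) loci track their partner's sense rate across
  conditions. All other genes have antisense rate exactly 0.
* **Counts.** Replicate counts are Poisson-lognormal: the per-library
  log-rate deviation has variance log(1 + φ) so mean and variance match
  a negative binomial with dispersion φ (default 0.1 — the study design
  does not pin down replicate overdispersion, so it is an exposed
  knob). One mixing family is used everywhere because coupled pairs
  share a log-normal latent factor: the focal antisense deviation is
  ρ·(partner sense deviation) + √(1−ρ²)·noise, which makes the
  across-library log-level correlation target ρ directly.
* **Strand error.** Every read (and, on the count-level fast path,
  every count) flips strand independently with probability
  `strand_error_rate` (default 0.005, the center of the 0.4–0.6% band
  junction QC estimates). The antisense count of a silent locus is
  therefore exactly Binomial(n, e) given its total — the caller's null
  is exact on generator data by construction.
* **Determinism.** Every operation draws from
  `default_rng([seed, op_code, library_index])`: any output is a pure,
  platform-stable function of (config, seed), and byte-identical across
  reruns.

What the generator does **not** emulate: sequence-level reads (no
FASTQ, no mapping ambiguity — mappability enters only through the
annotation-side track), positional coverage bias, UTR/isoform
structure, and real intron-size distributions. Passing tests therefore
demonstrate the statistics and bookkeeping of the pipeline, not
robustness to alignment artifacts in real data.

## Problem sizes used in validation

The acceptance suite runs: 1000 random binomial-tail cases (n ≤ 10⁴)
against a 50-digit summation oracle; all 2×2 Fisher tables with N ≤ 12
against exhaustive enumeration; exact Wilcoxon against rank-split
enumeration for groups ≤ 7; 300 replicate libraries × 3 error rates ×
~1.4 × 10⁴ junction reads for CI coverage (≥ 93%); 10 seeds of 5000
genes at 2 × 10⁶ reads/library for caller FDR/power plus 20 global-null
seeds; 100 coupled pairs × 8 libraries for mechanism recovery plus 20
null seeds; 200 seeds for occupancy-test calibration (KS uniformity)
and 200 genes/group for power; and an end-to-end demo of 400 genes × 4
libraries run twice for byte-identical determinism and truth recovery.
`scripts/acceptance.py` re-measures the same quantities at comparable
sizes (demo: 800 genes, 4 × 10⁵ reads) in about half a minute.

## Known limitations

* The binomial null conditions on the observed total n; loci where true
  antisense is a large fraction of n slightly inflate the background
  mean — negligible at p_bg ≈ 0.005.
* The NB-dispersion estimator needs ≥ 20 low-expression genes and can
  return "no overdispersion" on clean synthetic data, in which case
  calls use the binomial null.
* Per-pair correlations at 8 libraries have wide CIs; only pooled
  statements are reliable at that design size.
* The q-value of the SAM-style test is an FDR estimate, not a per-gene
  error probability; with few permutations (2v2) its resolution is
  coarse.
* Expression matching by rank-binned subsampling discards genes outside
  the common support; strongly disjoint distributions raise rather than
  silently match.
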
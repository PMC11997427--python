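# Methods

This note documents the statistical procedures pavscan implements, the
conventions adopted where a rule leaves room, what the synthetic cohorts do
and do not emulate, and the package's known limitations.

## Presence/absence calling

A gene's covered fraction in a sample is the number of exonic base
positions with read depth ≥ `min_depth` divided by the total exonic base
count; the gene is called present iff that fraction is ≥ `lost_cutoff`
(defaults 2 and 0.2). Conventions:

- **Inclusive boundary.** "At least 20% of exon regions" reads naturally as
  inclusive, so a fraction exactly equal to the cutoff is a presence call;
  this is unit-tested.
- **Base-level counting.** Exon coverage is counted per base, not per whole
  exon; overlapping annotated exons are merged on ingestion so shared bases
  are not double-counted.
- **Coordinates.** GFF3 (1-based inclusive) is converted to 0-based
  half-open internally. Depth files use the samtools-depth dialect: 1-based
  positions, zero-depth rows omitted; any position missing from the file —
  including positions beyond its last row — reads as depth 0.
- **Monotonicity.** Raising `min_depth` or `lost_cutoff` can only flip calls
  from present to absent; covered fractions are strand-independent. Both are
  property-tested.

## Pan-genome classification and rarefaction

Carrier frequency f = presence count / samples considered (all samples by
default; a population label restricts the denominator). The published
category intervals overlap at their endpoints, so they are resolved as
half-open intervals making the partition total: core f = 1 exactly;
softcore [0.99, 1); shell [0.01, 0.99); cloud (0, 0.01); genes with f = 0
go to a separate absent-everywhere bucket. Boundaries are evaluated on
integer counts (e.g. softcore iff 100·count ≥ 99·N and count < N), so
199/200 is softcore and 2/200 is shell with no floating-point ambiguity.

Rarefaction draws, for each sample size k, a fixed number of sample subsets
without replacement (default 100 replicates) and counts pan genes (present
in ≥ 1 sampled sample) and core genes (present in all). Means and standard
deviations (ddof = 1) are reported; per-k seeds derive from the global seed.
At k = N the subsample is always the full cohort, so the values are exact
with sd 0. No saturation law is fitted — the curve is reported as
means ± sd only, since any parametric form would be a modelling choice the
procedure does not need.

PAV distances: Hamming (fraction of differing calls) and Jaccard
(1 − |∩|/|∪| over present-gene sets, with two all-absent samples at
distance 0 by convention). The internal neighbor-joining tree (scikit-bio's
agglomeration behind the package's function) sorts samples canonically
before clustering so the topology is invariant to input order; additive
distance matrices are recovered exactly. For maximum-likelihood tree
building the binary matrix is exported as relaxed PHYLIP (sample ids exceed
strict PHYLIP's 10 characters) or FASTA of 0/1 characters.

## Selection scan

Per gene, the 2×2 table (present/absent × population A/B) is tested with a
two-sided Fisher's exact test under the minimum-likelihood convention (sum
of probabilities of all tables with fixed margins no more likely than the
observed one) — documented because doubling the one-tail is a common
alternative. q-values are Benjamini–Hochberg; genes absent from both
contrasted populations are untestable and excluded from the BH family,
shrinking m. A gene is flagged when q < 0.001 and fold > 2 (both strict),
where fold is the ratio of the larger to the smaller presence *frequency*
(equivalent to a count ratio only at equal population sizes; the frequency
ratio is the documented choice). When the smaller frequency is 0 the fold
is +∞ and qualifies only if the nonzero side has ≥ 2 carriers;
single-carrier contrasts are reported with `low_support = True` and never
flagged, preventing singleton artifacts.

Term enrichment: upper-tail hypergeometric P(X ≥ hits) with the universe as
population, BH across tested terms. Terms are flat labels; no ontology
graph propagation is performed.

## Population-genetic statistics

- **Locus filters**, applied and reported in order: mean depth in [2, 50]
  (when per-locus depths are supplied), missing rate ≤ 0.90 (inclusive:
  "more than 90%" is removed), minor-allele frequency ≥ 0.05 on non-missing
  calls (inclusive: "less than 5%" is removed). The composition is
  idempotent.
- **π** per site is the fraction of differing pairs among non-missing
  haploid alleles (n₁(n−n₁)/C(n,2)); the region value divides the summed
  per-site values by the full interval length in bp (the vcftools windowed-π
  convention), so monomorphic stretches dilute π rather than being skipped.
  A region whose every SNP has < 2 non-missing alleles has no defined π and
  raises rather than silently returning 0.
- **Fst** is the Weir & Cockerham (1984) two-population diploid estimator
  with observed heterozygosity in the variance components; per-site a, b, c
  are summed before the ratio (ratio of averages). Negative estimates are
  reported as computed; a region with no informative site raises. A fixed
  difference gives exactly 1; on Balding–Nichols cohorts the genome-wide
  estimate recovers the generating F (the model's expected Fst) within the
  stochastic tolerance stated in the tests.
- **Gene ± flank statistics** use three genomic-orientation intervals —
  [start−4000, start), [start, end), [end, end+4000) — truncated at
  chromosome bounds with a flag. Only SNPs strictly inside each interval
  contribute.
- **Windows** are fixed-origin half-open [k·w, (k+1)·w) with w = 10 kb by
  default; a site exactly on a boundary belongs to the right-hand window.
  Windows with no sites carry no score and never enter the quantile;
  terminal partial windows are kept and flagged.
- **Sweep regions.** The selection threshold is the nearest-rank empirical
  95th percentile (ascending rank ⌈q·n⌉) over scored windows, selecting
  scores ≥ threshold — nearest-rank was chosen because the procedure's
  quantile method is otherwise unspecified, and ties then select slightly
  more than 5%. Within a chromosome, selected windows separated by at most
  one intervening window merge into a region spanning first start to last
  end, scored by the maximum member; the merge is deterministic and
  idempotent. Genes are assigned to a region iff the gene body overlaps it
  by ≥ 1 bp (half-open on both sides).

## Expression and τ

FPKM[g,s] = counts·10⁹/(length·library), with library size the column sum
of assigned counts (featureCounts-style) unless supplied. τ is computed on
raw (not log) FPKM tissue means, as the index's xᵢ is simply "mean
expression". The implementation uses the summation form
Σ(1 − xᵢ/max)/(n−1), algebraically equal to the closed form
n/(n−1) − Σxᵢ/((n−1)·max) but exact at the limits: constant vectors give
exactly 0 and single-tissue vectors exactly 1 in floating point. The
identity between both forms is asserted to 1e−12 on random vectors. τ is
undefined (NaN, gene excluded) when all tissue means are zero — coercing to
0 would conflate "unexpressed" with "uniformly expressed". Argmax-tissue
ties break to the first tissue in sorted order and are flagged.

The τ ≥ 0.8 specificity threshold and the 1-FPKM expression floor are
package defaults (both configurable): no published cutoff accompanies the
index, so counts of specific genes depend on these settings and are
reported with them. Retention cross-tabs report per-tissue proportions of
pan-genome categories among specific genes (summing to 1, with an
unclassified bucket), and frequency distributions report per-population PAV
frequencies of each tissue's specific genes.

## Synthetic cohorts

The generators reproduce the statistical structure the pipeline assumes,
with one global seed fanned out to fixed per-generator child seeds
(`SeedSequence(seed, spawn_key=(k,))`), so adding a generator never
perturbs another and every output is byte-identical under a fixed seed.
Defaults mirror the motivating study design: 152 cultivated vs 49 wild
samples, nine chromosomes, 10× mean exon depth on a zero background, 50
planted selection genes, target Fst 0.3, an eight-tissue atlas.

- **Gene models**: 1–10 exons of 100–600 bp (total ≥ 300 bp), 50–300 bp
  introns, genes placed round-robin across chromosomes without overlap.
- **PAV cohort**: planted genes get the frequency pair (0.9, 0.1) between
  the two populations (direction randomised; fold 9 > 2); null genes share
  one frequency drawn from a pan-genome-like mixture (80% at 1.0, 10% on
  (0.95, 1), 10% on (0.05, 0.95)) chosen so most genes are core, as in real
  crop pan-genomes.
- **Coverage**: per-base exon depth ~ Poisson(mean). Poisson is a modelling
  choice — real depth is overdispersed and spatially correlated
  (mappability, GC) — so recovery rates on these tracks bound what the rule
  can do on clean data, not on real alignments.
- **Genotypes**: Balding–Nichols — ancestral p ~ U(0.1, 0.9), population
  frequencies Beta-distributed around p with parameter F, diploid binomial
  genotypes — chosen because it gives a closed-form target Fst. F = 0
  degenerates to equal frequencies without a Beta draw.
- **Expression**: specific genes at mean 100 in one tissue and ρ·100
  elsewhere (ρ ~ U(0, 0.1), noiseless τ = 1 − ρ ≥ 0.9); null genes at
  m·U(0.9, 1.1) per tissue (noiseless τ ≤ ~0.21); replicates multiply
  log-normal noise (σ = 0.2).
- **Window scores**: Exponential(1) background with planted runs of 1–3
  windows above the background's 99th percentile, separated by ≥ 4 windows
  so distinct runs cannot merge.

What passing tests show: the implementations compute their statistics
exactly (oracle agreement) and recover planted structure under clean,
well-separated conditions. What they do not show: robustness to
overdispersed coverage, batch effects, LD, population structure beyond the
two-group model, or annotation errors in real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale: a
200 × 60 PAV recovery cohort, 5,050-gene scans over 20 seeds, 5,000-SNP
Fst cohorts, exhaustive Fisher enumeration to margins of 30, and 1,500
windows per sweep-recovery replicate — sizes chosen so each stage's
statistical target (3 standard errors, or exact agreement) is already
decisive. Fisher p-values come from scipy's exact routine and were verified
against exact integer enumeration over all 246,015 tables with margins
≤ 30 (max |Δ| ≈ 6e−16); BH uses statsmodels' step-up behind the package's
function and is checked against the textbook definition. Stochastic
assertions use fixed seeds throughout; Monte-Carlo tolerances are stated as
multiples of the standard error they estimate.

## Limitations

- PAV calling consumes precomputed depth tracks, not BAMs; alignment and
  depth extraction are upstream.
- Sweep scores (e.g. XP-CLR) are consumed as given; the composite
  likelihood itself is out of scope, as are ML tree search, admixture
  inference, GWAS and differential expression.
- The Fst estimator is the two-population form; multi-population contrasts
  must be run pairwise.
- Classification treats "individuals" as whichever sample set the caller
  passes; per-population classification changes the denominator and hence
  the categories.
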
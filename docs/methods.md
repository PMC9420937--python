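# Methods

## Coordinate and identity conventions

All coordinates are 0-based, half-open (BED-native).  A single-strand break
between bases N and M in 5′-NM-3′ is assigned to base N, so a break position
is the 0-based coordinate of N together with the strand the nick was read on.
Position identity includes the strand: the same coordinate on opposite
strands is two distinct positions, and deduplication within a replica never
collapses across strands (the template/non-template analysis requires
stranded positions).  A break "overlaps a repeat" iff base N lies inside a
repeat interval; the base across the nick is not consulted.  Interval sets
are stored merged per chromosome, and book-ended intervals merge (coverage
semantics: downstream statistics only ever ask whether a base is covered).

"Within ±200 bp" is inclusive at both ends everywhere (|distance| ≤ 200,
closed windows of 401 bases including the anchor base), applied consistently
to operative-TSS search, enrichment counting, window lengths, and the
element hierarchy.

## Hotspot model

A replica is a deduplicated set of stranded positions after repeat
filtering.  Support of a position is its multiplicity across replicas;
hotspots are positions with support ≥ k, k ≥ 2.  The shared fraction is
|support ≥ k| / |support ≥ 1|.

The chance level of sharing is estimated by Monte-Carlo: each of `n_sim`
(default 100) simulations redraws every replica's observed position count
uniformly *without replacement* from a space of S equally likely positions
and records the simulated shared fraction.  S defaults to 2·LG, the number
of stranded non-repeat positions (LG = non-repeat genome length).  This is
the least-assuming null — every detectable position equally breakable — and
S is an explicit parameter so that an observed-position-pool null can be
substituted.  Significance is a two-sided one-sample Student t-test of the
`n_sim` simulated fractions against the observed fraction: the simulations
are the only exchangeable sample available, so they form the t-test's
sample.  A zero-variance null (possible at tiny S) falls back to exact
comparison and is flagged.

Uniform sampling without replacement is implemented as with-replacement
draws deduplicated in first-occurrence order, which is distributionally
identical to sequential rejection sampling.  Weighted sampling without
replacement (the generator) uses exact Gumbel top-k perturbation on the
log-weight field.

Cross-cell-type hotspot overlap is summarized as OR = observed / (|A|·|B|/U)
over a universe of U positions with a two-sided binomial test
(x = observed, n = |A|, p = |B|/U).  Percentages in summary tables round
half-up to one decimal.

## Operative TSS and strand classes

CAGE tags from multiple files are combined by summing depths at identical
(chromosome, coordinate, strand); tags with depth ≥ 2 are peaks.  A gene's
operative TSS is the maximum-depth peak within ±200 bp of its annotated TSS
*on the gene's strand* (a capped 5′ end defines a TSS only on its own
strand).  Genes without a qualifying peak are not expressed and take no part
in TSS-centric statistics.  Ties on depth break by minimal distance to the
annotated TSS, then by the 5′-most coordinate on the gene strand; the
tie-break is fixed purely for determinism.

A break on the strand opposite a TSS is a template-strand match (the
transcribed strand); same strand, non-template.

## Metagene profile and enrichment ratio

For every position the signed distance to the nearest operative TSS is
computed (absolute-shortest wins; ties break toward the lower genomic
coordinate), negative 5′ of the TSS in gene orientation.  The ±5,000 bp
region is split into 500 non-overlapping 20-bp bins; bin j covers oriented
offsets [−5000 + 20(j−1), −5000 + 20j), so the TSS base sits at the left
edge of bin 251.  The average non-repeat ratio NR_j over the n expressed
genes uses each gene's per-bin non-repeat base count LNR_kj/20; bases beyond
a chromosome end count as unusable.  Densities are
D_ij = N_ij·10⁶/(NR_j·T_i) with T_i the sample's genome-wide position count
("total positions in the sample" is read genome-wide; bins with NR_j = 0 are
reported missing, not zero).

The enrichment ratio R_i = (M^200/M^5000)/(L^200/L^5000) counts positions by
|nearest-TSS distance| and sums window lengths per gene (overlapping windows
of nearby genes count once per gene, mirroring the per-gene construction of
NR_j).  Its p-value is a two-sided binomial test conditioned on the
in-window count M^5000 — the arrangement that matches the ratio's structure.
Treatment groups are compared by a two-sided Welch t-test of per-sample
combined-strand ratios against a reference group; Welch is chosen because
per-treatment samples are few and their variances need not match.

## Element hierarchy

Seven classes consulted strictly in order: TSS ±200 (operative TSSs of
expressed genes), CAGE peak ±200 (all called peaks), chromatin-state
promoters (externally provided intervals, merged), TTS ±200, exonic,
intronic (all three from the longest transcript of every annotated gene,
irrespective of expression), and intergenic (the complement).  Each position
gets the first matching class.  OR_i = (M_i/T_i)/(L_i/LG) with a two-sided
binomial test.  L_i is measured on each class's own merged interval set by
default — "the total non-repeat length of the genomic element" — with a
priority-disjoint variant (each class minus all higher classes) behind
`disjoint_lengths=True`.  Only the disjoint variant makes uniform random
breaks give OR = 1 for every class, because classes 1–3 overlap heavily;
calibration checks therefore use it, and both are emitted for sensitivity.

## Expression stratification

Genes rank by mean expression over replicate columns; the top 5/10/25/50%
strata are nested, ties broken by gene identifier.  Expected fractions come
from uniform random stranded positions over the non-repeat genome (the
reference analysis drew 11,687,672; here the count is a recorded parameter,
200,000 by default — ample on megabase genomes).  OR = observed/expected per
stratum and distance bin (±200, and the annulus 200 < |d| ≤ 5000).
Hotspot-vs-breaks comparisons use a one-sided two-sample Student t-test over
the four strata ORs (the series the figures plot).

## Sequence context

Contexts are 2·flank-base windows on the break's strand with the nick
between positions 0 and 1 (position 0 = base N); minus-strand windows are
reverse-complemented, so label 0 always sits at string index flank−1.
Windows running past a chromosome end are dropped and counted; lowercase
bases are uppercased (masking is the repeat filter's job upstream); contexts
with ambiguity codes are excluded from the matrix and counted.  Information
content per position is 2 + Σ f·log₂f bits.  C/G ratios are reported at
positions −1 and 0; a median helper aggregates an explicit list of matrices
(which matrices enter a median is the caller's choice).

## Synthetic data generator

The generator emulates the statistical structure the analysis is designed to
detect, at desk scale (defaults: 2 chromosomes × 5 Mb, 500 genes, 4
replicas, 10⁵ breaks each, 20% repeat fraction, hotspot gain 1000 on 500
planted positions, TSS enrichment factor 3, cytosine bias 0.25):

- **Genome**: i.i.d. uniform ACGT sequence; repeat intervals (200–2,000 bp)
  placed and trimmed so the merged repeat length per chromosome equals the
  configured fraction exactly.
- **Slot geometry**: each gene occupies its own slot; the slot's right end
  holds a repeat-free "promoter sanctuary" (11.8 kb) from which the TSS is
  drawn.  Consequently ±5 kb windows around TSSs are repeat-free and never
  overlap a neighbouring gene's window.  This encodes the repeat depletion
  of real promoters and makes the planted rate boost exactly what the window
  statistics estimate; it also means the generator does not exercise
  window-overlap or window-repeat corner cases (the unit tests cover those
  with hand-built genomes).
- **Breaks**: each replica draws its positions without replacement from a
  weight field over all stranded non-repeat positions — baseline 1,
  × (1 + (f−1)·j_g) within ±200 bp of gene g's TSS (j_g a mean-1 lognormal
  jitter, so the neutral factor f = 1 yields an exactly uniform field),
  × hotspot gain on planted positions shared by all replicas.  A
  `cytosine_bias` fraction of draws is taken from the sub-field of positions
  whose strand base is C, so the motif signal is carried by the emitted
  sequence itself.
- **CAGE and expression**: the deepest CAGE peak is planted at each
  annotated TSS with strictly shallower satellites within ±200 bp;
  expression is lognormal, coupled to the promoter jitter through a Gaussian
  copula with correlation `expression_coupling` (0 = independent).
- Everything derives from one root `SeedSequence`; a fixed seed fixes every
  emitted file bit-for-bit.

What the generator does *not* model: library chemistry, PCR and sequencing
error, mappability structure, chromatin-driven break clustering beyond the
planted promoter boost, GC heterogeneity, overlapping genes, and realistic
repeat families.  Passing tests therefore demonstrate correctness of the
statistics on data with known structure, not robustness to every artifact of
real libraries.

## Validation strategy and problem sizes

The test suite checks, on synthetic conditions chosen once: worked-example
arithmetic on published counts; recomputation identities for every emitted
D_ij, R and OR row; equivalence of hotspot counting, element priority and
the Monte-Carlo null with brute-force oracles (exhaustive enumeration at
S = 4); null calibration with uniform breaks (10⁵ breaks, 500 genes,
2 × 5 Mb: R and all disjoint-mode element ORs within [0.9, 1.1]); recovery
of planted enrichment factors 2 and 5 within ±15% (12 replicas × 5 × 10⁴
breaks, exact per-gene multipliers; the R statistic saturates as
f·r₀/(1 + (f−1)r₀)/r₀ with r₀ = 401/10001 ≈ 0.04, an expected −13.8% at
f = 5, which is why the per-replica depth is kept moderate and replicas are
averaged); planted-hotspot sensitivity ≥ 0.95 with the real-vs-null excess
significant; cytosine-bias detection at position 0; and byte-identical
outputs across repeated pipeline runs from one seed.  These sizes keep the
whole suite at a few minutes on one CPU.

## Known limitations

- The operative-TSS tie-breaks, the bin-boundary convention, the t-test
  orientation of the null comparison, and the binomial-test conditioning are
  fixed choices among defensible alternatives; all are documented above and
  localized so sensitivity analyses can swap them.
- Whether element lengths L_i should be own-set or priority-disjoint is
  genuinely ambiguous; both are first-class.
- Genome-scale results from the underlying assay (hundreds of thousands of
  hotspots, per-cell-type ratios) require the deposited sequencing data and
  reference annotation; this package reproduces the statistical machinery
  and validates it on planted-truth synthetic data.
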
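# Methods

`chromlink` separates two gene-regulatory programs in a three-lineage
(ectoderm, endoderm, mesoderm) pseudo-bulk multi-omic dataset:
developmental genes, which are dominated by one lineage and regulated by
distal lineage-specific chromatin, and housekeeping-like genes, which are
expressed evenly and regulated proximally. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## The dominance index

Every classification in the package reduces to the Berger-Parker dominance
of a triple of non-negative values,

    Dom(v) = max(v) / (v1 + v2 + v3),    Dom in [1/3, 1],

applied to linear-scale expression (genes), GpC accessibility levels
(100-bp windows) and CpG hypomethylation levels (500-bp windows). The same
implementation serves all three, so range and scale-invariance properties
are tested once.

* **Genes.** Input expression is log2 RPKM and is linearised (`2**GE`)
  before the ratio: ratios of log values are meaningless around zero, and
  linearisation reproduces Dom = 0.33 for an even triple. A gene is
  `DEG_<lineage>` when Dom >= `d_high` (0.6) and the dominant lineage
  exceeds the expression floor `deg_min_expr` (log2 RPKM > 2, matching the
  pool used by the threshold permutation test); `SEG` when Dom <= `d_low`
  (0.34, "almost even"; 1/3 is exact evenness) and all lineages are
  expressed (`seg_min_expr`, log2 RPKM > 0). Both bounds are inclusive so
  the worked boundary values classify. Threshold comparisons carry an
  absolute tolerance of 1e-9 so the log2/linear round trip cannot flip an
  exact boundary case. Genes whose linear expression sums to zero have
  undefined dominance and are excluded, not classified.
* **Accessibility.** Level = methylated GpC / total GpC per lineage
  (NOMe-seq: methylated GpC marks open chromatin). Dom >= 0.6 calls a DAR
  of the argmax lineage; Dom <= 0.34 calls a SAR, split at mean level 0.35
  into high- (HA) and low-accessible (LA). Each qualifying window is one
  region; merging of book-ended windows exists behind a flag but is off,
  keeping region counts at window resolution.
* **Methylation.** M_i is the methylated CpG fraction in 500-bp windows.
  The printed dominance formula on M_i would label the most *methylated*
  lineage while the products are described as hypomethylated regions; the
  default polarity therefore computes dominance on h_i = 1 - M_i so the
  dominant lineage of a DhMR is the most hypomethylated, and an ShMR
  additionally requires low methylation overall (mean M < `shmr_ceiling`,
  0.5 — "similarly low" has no printed cutoff). The literal polarity is
  retained as an option for auditability.

An "almost even" call is a stringent criterion: Dom <= 0.34 tolerates only
about 2% relative imbalance between the three values. Continuous
pseudo-bulk expression can meet it; window levels estimated from tens of
dinucleotide counts rarely can (a binomial level with n ~ 12-25 needs a
near-exact count tie), so SAR/ShMR sets are small at desk-scale coverage.
This is a property of the statistic at that coverage, not of the
implementation; DAR/DhMR calling, whose criterion is one-sided dominance,
is unaffected.

## Window QC

Accessibility windows pass three filters per lineage triple: (1) coverage,
reads > 25 and reads per GpC dinucleotide > 2; (2) coverage balance;
(3) GC-count balance. The printed balance inequalities
(`|max|cov_i - cov_j| - mean| < std`, 3-sigma analogue for GC counts) are
unsatisfiable for perfectly balanced windows — the left side then equals
the mean while the std is zero — so the default variant interprets
"variability less than one standard deviation over mean" as a coefficient
of variation: std/mean < 1 for coverage and < 3 for GC counts, with the
sample (n-1) standard deviation of three values. The literal variant is
kept selectable so the printed form can be audited. The filter chain is
monotone and every stage logs counts.

## Permutation tests

All permutation p-values use the add-one convention (k+1)/(n+1), except
that zero exceedances at n permutations are reported as 1/n (0/1000 prints
as p = 0.001). The dominance-threshold test assembles random triples by
drawing one gene's value per lineage, independently and uniformly, from a
pool of expressed genes (any lineage for the SEG test; log2 RPKM > 2 in
the conditioning lineage for the DEG test; pools under 10 genes are an
error). Set-enrichment folds compare an observed overlap with redraws of
equal-size sets from the universe; TAD co-occurrence shuffles class labels
over fixed gene positions; region-clustering nulls circularly shift one
region set within each chromosome.

Calibration: p-values of tests with continuous statistics (dominance) are
uniform under their null and are checked by Kolmogorov-Smirnov over 1,000
replicates. Integer-valued statistics (mixed-TAD counts, small-set
overlaps) have atomic null distributions, so their p-values are discrete
and conservative rather than exactly uniform — a KS test against the
continuous uniform would reject them by construction. For those tests the
suite verifies level control instead: the rejection rate at alpha = 0.05
under the null stays at or below the level (within Monte-Carlo slack).

## Genome architecture

Nearest-neighbour distances order genes by TSS per chromosome and take the
minimum adjacent gap; chromosome-terminal genes use their single gap and a
chromosome's only retained gene is undefined (NaN). The expression filter
(thresholds swept over -3..3 log2 RPKM) applies to the neighbour set, not
only the focal gene, so raising the threshold is monotone in every
retained distance. DEG-vs-SEG distance and TAD-statistic comparisons use
the two-sided Mann-Whitney test. TAD membership is half-open containment
of the TSS (a TSS exactly on a boundary belongs to the TAD starting
there); gene density is genes per 100 kB. CG-rich promoters use
CpG-island-style criteria — GC fraction > 0.5 and CpG observed/expected
> 0.6 over at least 200 bp — on a strand-aware promoter window, with a
one-tailed Fisher test between gene classes.

## Chromatin abundance coefficient and linking

For a gene set and vicinity half-width V, each gene's open-region count
within +/-V of its TSS is normalised by the expressed genes in that
vicinity, f_i = N(V_i)/Ng(V_i); genes are grouped by f at count resolution
(f rounded to integer — the grouping "within the same normalised frequency
counts"; the rounding is configurable) and the CAC is the Pearson r
between group frequency and group mean log2 expression. Fewer than three
distinct groups leaves r undefined. Matched lineage pairing is the
caller's responsibility (mesoderm DARs around mesoderm DEGs, and so on).

The zone of influence Z* is the grid vicinity (default 20-400 kB)
maximising r *while keeping high enough region density*: a candidate
vicinity's mean per-bp region count must stay within `density_floor`
(default 0.85) of the grid maximum. The constraint matters because the
per-bp density is flat for vicinities inside the true regulatory zone and
decays beyond it (extra span adds only background), while the correlation
alone can stay high well past the zone; the density plateau edge is
effectively an estimator of the zone scale. Ties in r break toward the
smaller vicinity — the more local explanation.

Linking then pairs gene g and region r iff |TSS_g - centre_r| <= Z* and
both lie in the same TAD. The TAD predicate is not optional; it is what
lets the method work without chromatin-contact data. Region positions are
interval midpoints everywhere; output distances are signed and
strand-aware (positive downstream), predicates use absolute distance.
Histone-mark peak sets (e.g. H3K27ac) run through the identical scan with
peak centres in place of regions.

## Motif repertoires

Each of the eight region sets carries a list of enriched motifs ranked by
a single enrichment score column (by default -log10 p from upstream
enrichment tools; any monotone statistic gives identical ranks). Motifs
whose origin TF gene is not expressed (log2 RPKM <= 0 in all lineages) are
dropped. A list becomes a vector over the motif union: quartile ranks 1
(top quarter) to 4 by a ceiling partition (a 5-item list splits 2,1,1,1),
0 for absent motifs. Similarity is the RMSE between vectors over the full
union, zeros included — absent motifs are informative. Group structure is
the between-minus-within median pairwise RMSE gap, tested by a Welch
t-test on pairwise values, a label permutation, and a GC-stratified
permutation that shuffles each vector's entries only among motifs in the
same union-GC quartile (housekeeping-associated motifs are systematically
GC-richer, so an unstratified null conflates repertoire and composition).
IUPAC degenerate consensus symbols contribute fractionally to nucleotide
and dinucleotide content (R is half A, half G); dinucleotide entropy is
-sum Pxy log2 Pxy over adjacent pairs, 0 for homopolymers and at most 4
bits. Signature sets: housekeeping = intersection of top-quartile motifs
of the SEG enhancer and promoter lists; developmental = union over
lineages of the per-lineage enhancer/promoter top-quartile intersections.

## The synthetic data generator

The generator emulates the statistical structure the pipeline needs to be
testable, with planted ground truth:

* **Expression** is Normal in log2 RPKM (mu = 4, sigma = 2.5 between
  genes; heavy-tailed in linear RPKM). A planted DEG has two off-lineages
  at Normal(1, 0.8) and the dominant lineage boosted by delta = 4 log2
  (16-fold), giving Dom >= 0.6 in >= 95% of draws (checked against a
  Monte-Carlo closed form). A planted SEG shares one baseline
  (Normal(4, 1.5), floored at 0.5 so the SEG expression floor is met) with
  within-gene lineage noise of 0.01 log2 — the evenness criterion derives
  this scale: P(Dom <= 0.34) ~ 0.997 at s.d. 0.01 but only ~ 0.8 at 0.02.
  Background genes share a baseline with 0.5 log2 lineage noise; fully
  independent lineage draws would make a large fraction of background
  genes spuriously dominant, which neither matches lineage-correlated real
  transcriptomes nor leaves the planted classes identifiable.
* **Placement** alternates two TAD types along each chromosome: 400-kB
  TADs holding one isolated DEG at their centre, and 300-kB TADs holding
  dense clusters (8 genes, ~5-kB exponential gaps) of SEGs and background
  genes. By construction the median nearest-expressed-TSS distance of
  DEGs exceeds that of SEGs on every dataset.
* **Accessibility** windows (100 bp) get per-lineage reads ~ Poisson(50),
  GpC totals ~ Poisson(12) and binomial methylated counts: open means
  level ~ 0.75, closed ~ 0.08, proximal SEG regions ~ 0.5 in all lineages,
  background ~ 0.15. Each DEG receives Poisson(2 x GE-decile) planted open
  windows uniform within +/-100 kB of its TSS (the planted zone length L);
  each SEG receives Poisson(3) within +/-2 kB. The uniform kernel is the
  simplest whose density plateau ends at L, which is what the zone scan
  estimates.
* **Methylation** windows (500 bp) are anti-correlated with accessibility:
  half of the planted DARs get a window hypomethylated (M ~ 0.15) in the
  open lineage and methylated (~0.85) elsewhere; SEG promoters get evenly
  hypomethylated windows; background is evenly methylated (~0.75).
* **Motif lists** draw from a developmental and a housekeeping grammar
  sharing `motif_overlap` (0.2) of their motifs; housekeeping consensi are
  GC-rich (p(G/C) = 0.75 per position) with probability `gc_split` (0.9),
  developmental ones with the complementary probability. 25% of motifs are
  assigned non-expressed origin TF genes so the expression filter has
  something to drop. Scores are descending -log10-p-like draws.

Identical spec and seed give byte-identical outputs (single `numpy`
Generator, fixed iteration order).

What the generator does **not** emulate: read-level or sequence-level
data (no FASTA/FASTQ; promoter GC classification takes sequences or
precomputed stats supplied by the caller), single-cell structure (the
assay is consumed as pseudo-bulk, as in the analysis it supports),
distance-decaying enhancer kernels, inter-chromosomal differences, and
realistic genome-scale region counts. Passing tests therefore demonstrate
correctness of the statistics and recovery of planted structure under
these study conditions, not performance on a real gastrulation dataset.

## Problem sizes and defaults

Default datasets use 300 genes on three 16-Mb chromosomes (~2,000
accessibility windows, ~1,000 methylation windows); the zone-of-influence
benchmark uses 300 genes on one 50-Mb chromosome with Poisson(5 x decile)
planted regions and 300 uniform background regions, scanned over
{20, 40, 80, 120, 160, 200, 300, 400} kB. Oracle-equivalence tests run on
50-gene instances where brute-force double loops are exact. These sizes
keep the full suite and the acceptance script fast while leaving every
statistic estimable.

## Known limitations

* SAR/ShMR calls are scarce under realistic count noise (see above); the
  pipeline's SAR-side spatial statistics are exercised mainly through
  planted proximal regions and the ShMR set, not through large SAR sets.
* The zone scan's density floor (0.85) is a declared constant; kernels
  with long decaying tails would blur the density plateau the constraint
  relies on.
* The MAD fold-change DEG strategy uses a robust z-score
  ((d - median)/(1.4826 MAD)) as the dispersion estimate; with a
  degenerate (MAD = 0) difference distribution it falls back to percentile
  ranks with a warning.
* CAC grouping at integer count resolution is a declared choice; very
  sparse region sets can leave fewer than three groups, in which case the
  correlation is flagged undefined rather than extrapolated.
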
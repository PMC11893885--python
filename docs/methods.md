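# Methods

This note documents the models, parameter choices and numerical
conventions behind `enhdyn`, and what the synthetic-data suite does and
does not establish about behavior on real data.

## Coordinates and formats

All intervals are 0-based half-open (BED convention) everywhere; adjacent
intervals never overlap, and every overlap question defaults to "≥ 1 bp
shared" unless a caller overrides `min_bp`.  CTSS tables in 1-based
dialects are converted on read.  The genome is a plain chromosome-size
table; no named assembly is assumed.

## Bidirectional enhancer calling

Tag clustering is single-linkage over per-strand CTSS positions: tags
≤ `max_gap` (default 20 bp) apart join a cluster; clusters with fewer than
`min_count` (2) tags are dropped.  This deliberately replaces
decomposition-based peak calling with the simplest procedure that
preserves the quantity downstream steps consume — stranded tag clusters.

Pairing scans each minus-strand cluster for the nearest plus-strand
cluster starting at or right of its end (divergent orientation); the
inner gap must be ≤ `pairing_window` (400 bp).  When one minus cluster
could pair with several plus clusters, the nearest wins.  The
directionality score D = (F − R)/(F + R) uses the paired clusters' total
tag counts; loci are kept when |D| < 0.8 strictly, so F > 0 and R > 0 by
construction.  Loci overlapping the promoter catalog padded by ±500 bp
are discarded (divergent transcription at TSSs would otherwise dominate
the calls); overlapping surviving loci are merged keeping the smaller
|D|.  The window, threshold, gap and padding are all exposed; the
defaults follow the established bidirectional-eRNA definition in the
field.

## Expression

Counting is strand-specific for stranded regions (promoters); unstranded
regions (enhancers) always sum both strands.  CPM uses raw prior-adjusted
library sums — CPM_ij = 10⁶(c_ij + 0.25)/Σ_i(c_ij + 0.25) — with no
compositional (TMM-style) correction, so a strongly asymmetric DE burden
can shift library sizes slightly; at the simulated DE fractions this
costs a few points of empirical FDR but leaves type-I error at the
nominal level under the null.  Expression filters use strict inequality
(log₂ CPM > −2 for promoters, > −2.5 for enhancers, in ≥ 1 sample).

The temporal test is a likelihood-ratio ANOVA for NB counts:
per-feature means per timepoint (alternative) against a common mean
(null), both with log library-size offsets, fitted by Fisher scoring
with fixed dispersion, and compared to χ² with (groups − 1) df.
Dispersion is method-of-moments with two corrections that matter at
n = 2 replicates per group: the squared-mean term is de-biased for the
sampling variance of group means, and the global shrinkage center is a
ratio-of-sums estimator rather than a median of per-feature ratios (the
naive version underestimates dispersion by ~25% at these sizes and
inflates type-I error to ~0.11; the corrected estimator restores
0.05 ± 0.01).  Per-feature estimates are shrunk toward the global value
with `prior_df = 20` pseudo-degrees of freedom against the residual df.
Features with zero total count get statistic 0, p = 1.  FDR is
Benjamini–Hochberg at 0.05.

Clustering z-scores each DE feature's profile across samples, runs
k-means (k = 4, 10 restarts, fixed seed), and relabels clusters
deterministically by Hungarian assignment of centroid timepoint profiles
to four archetypes — (high, low, low), (high, high, low),
(low, high, high), (low, low, high) — giving the semantics 1: down from
Day 3, 2: down at Day 6, 3: up from Day 3, 4: up at Day 6.  Constant
profiles cannot be z-scored and are excluded with a warning.  Promoter
statistics use total-RNA libraries, enhancer statistics nascent-RNA
libraries; the two assays are never pooled in one test.

Nearest-promoter assignment is midpoint-to-midpoint with ties broken
toward the lower start coordinate; enhancers on promoter-free
chromosomes map to nothing and count only in row denominators of the
cluster-overlap matrix.

## Interaction calling

Restriction fragments are replaced by fixed-width 2 kb other-end bins
(configurable); trans contacts and distances beyond 2 Mb are dropped; a
pair with both ends in probe regions supports both anchors once each.

The background is empirical: for each replicate, the support values of
all (negative-control anchor, bin) slots — zeros included — are pooled
into 20 log-spaced distance bins (bins with < 50 slots merge upward), and
the tail probability of an observed support k at distance d is
(#{background slots in d's bin with support ≥ k} + 1)/(N + 1).  The +1
pseudocount keeps p > 0 with a finite control sample, so p_min = 1/(N+1).

Candidate slots are those with support ≥ 5 in **both** replicates.
Multiplicity is corrected per anchor: m_a = the anchor's candidate count,
p_bonf = min(1, p·m_a).  A run-wide Bonferroni over all candidate slots
would interact with the empirical p-value floor to make every call
impossible at desk scale (threshold 0.1/m ≪ 1/(N+1)); per-anchor
correction matches the source method's design, in which each captured
target is its own small family of tests.  The run-wide candidate count is
still reported.  A call passes when support ≥ 5 *and* p_bonf ≤ 0.1 in
each replicate separately — the strictest reading of "in both
replicates".  Calls whose distal bin overlaps a blacklist are removed
before testing.

"Interaction frequency" of targets vs negative controls is compared as a
2×2 proportion-equality test with continuity correction (Yates χ²).  For
calibration the proportions are support-filtered candidate slots per
total testable slots per class (stable even when no call passes under a
pure-background simulation, where the fold is ≈ 1 by construction); the
significant-call rate per class is reported alongside.

Networks connect an anchor to every feature overlapping its distal bin
when the call passes in at least one replicate; unannotated bins remain
as synthetic `bin:` nodes.  JI and OCE are as defined in the README;
both are symmetric in network order, OCE ≥ JI always, and a node whose
smaller neighbor set is empty has OCE 1 (pure loss or gain is not
"rewiring" under OCE — only partner exchange lowers it).  The
DE-vs-non-DE comparison of per-node OCE (and JI) uses a two-sided
Wilcoxon rank-sum test, and the contact-timepoint expression coupling
uses Pearson correlation on log₂ CPM (Spearman by flag); both choices
stand in for tests the motivating analyses leave unnamed.

## GWAS enrichment and characterization

LD expansion includes proxies with r² ≥ 0.7 within 1 Mb; loci sharing
proxies merge.  Matching covariates are MAF decile, LD-proxy-count bin
(0, 1–2, 3–5, >5) and distance-to-nearest-gene tertile, widened in that
reverse order (gene distance first, MAF last) with a warning whenever a
bin cannot supply `min_neighbors` controls.  The permutation test
replaces every index SNP with a random matched control, expands the
control by *its own* proxies, recounts loci with ≥ 1 proxy in the
regions, and reports p = (#{permutations ≥ observed} + 1)/(n + 1) — never
0 — with fold = observed / permutation mean.  Note that LD expansion
attenuates fold estimates toward 1 (both observed and control loci can
hit via proxies), and that matching on proxy count deliberately absorbs
enrichment that is mediated by SNP density rather than by the trait.

Matched random regions reproduce the template's length multiset exactly;
placements are uniform over the genome, rejected while overlapping any
excluded region (telomere/centromere stand-ins), and reproducible by
seed.  Conservation means are base-weighted over bedGraph segments with
uncovered bases excluded; group comparisons are Wilcoxon rank-sum.
Nucleotide diversity is π = 2·AF·(1 − AF) per SNP, averaged per region
(0 for SNP-free regions); before log₁₀ the smallest non-zero regional
mean is added to every mean so the log is always defined.  eQTL overlap
is a 2×2 Fisher's exact test of in-region vs random-set SNPs.

## qPCR arithmetic

ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt is computed on mean
ΔCt per condition against the control condition; fold = 2^(−ΔΔCt), with
per-replicate folds reported for the SEM.  Condition comparisons are
one-way ANOVA on ΔCt followed by Dunnett's test against the control.

## The synthetic-data generator

The generator emulates the study design, not its scale: a 2 × 10 Mb
genome with 300 promoters (40 bp, strand purity 0.95) and 200 enhancers
(two 180 bp flanks around a 40 bp gap, per-locus strand balance
Beta-distributed around 0.5), 3 timepoints × 2 replicates × 2 assays.
Feature counts are negative-binomial (dispersion 0.1) around
cluster-specific temporal means; the default temporal effect is 4-fold
between the high and low levels, with half the features DE split equally
across the four patterns by exact quota.  Enhancer mean expression (60)
is 5-fold below promoters (300), and eRNA leaks into total-RNA libraries
at 5% of its nascent rate.

Hi-C background counts per (anchor, side, distance-bin) slot are Poisson
with mean proportional to d^(−1) (exponent configurable), identical for
every probe class — negative controls carry background only.  A planted
contact multiplies the expected support of its slot by λ (default 8) at
its active timepoints in both replicates, with both read ends placed
inside the partner features so both anchors accumulate support.  Planting
is promoter-centric: each selected promoter receives two enhancer
partners 20–300 kb away; flat promoters keep both at all timepoints,
while DE promoters swap partners between their high and low timepoints —
this is what makes OCE discriminate DE from non-DE nodes, since OCE only
drops on partner exchange.  Features joined by an active contact also
share a lognormal expression factor (σ = 0.5) at that timepoint only,
which is what the contact-timepoint correlation analysis detects.

Variants are uniform at 2×10⁻⁴ per bp with AF ~ Beta(1, 3); enhancer SNP
density can be scaled by a factor; LD is assigned within blocks with r²
decaying exponentially in distance.  GWAS index SNPs land inside
enhancers `gwas_enrichment`-fold (default 3) more often than a pool SNP
would; eQTL flags are elevated inside enhancers (2×).  Conservation is
piecewise-constant: 500 bp background windows around mean 0.2 (σ 0.08),
enhancer segments shifted up by 0.3, all clipped to [0, 1].

What the generator does **not** model: read-level sequence, mappability
and GC biases, restriction-fragment geometry and ligation artifacts,
assay efficiency differences between libraries, population LD structure
beyond block-local decay, and any coupling between conservation and
variant density.  Passing calibration here therefore shows the
statistics are implemented correctly and calibrated against their own
stated assumptions — not that those assumptions hold in any particular
real dataset.

## Calibration study conditions and problem sizes

The standing problem sizes were chosen so each suite's statistic is
informative at desk scale:

- **Interaction caller** — 500 target anchors, 200 negative controls,
  2 replicates, 1200 pairs/anchor, one timepoint.  Pure background
  (no planted contacts): ≤ 0.1% of candidate slots may pass and the
  target-vs-negative fold sits in [0.8, 1.25].  Planted λ = 8 contacts
  at 20–100 kb (expected support ≥ 10): recall ≥ 0.8, precision ≥ 0.9.
- **DE test** — 2000 features, 3 × 2 design, mean 100, dispersion 0.1:
  null raw-p < 0.05 fraction within [0.03, 0.07], FDR < 0.05 fraction
  ≤ 0.01, p-values uniform (KS); 400 planted 4-fold features among 1600
  flat: power ≥ 0.8.
- **Clustering** — 4 × 100 features at 4-fold effect, dispersion 0.1:
  ARI ≥ 0.8 against the planted labels (and exact archetype naming on
  near-noiseless profiles).
- **GWAS enrichment** — 100 index SNPs over an 8000-SNP pool, enhancers
  covering ~10% of the genome, negligible LD, 200 permutations: the
  null p is uniform over 200 seeds (KS), and a planted 3× enrichment
  yields fold within [2, 4] at p ≤ 0.05.  The enhancer span and weak LD
  are what keep the permutation statistic non-degenerate (enough hit
  mass) and the fold un-attenuated (no proxy leakage), respectively.
- **End-to-end** — the default configuration above; the run report's
  percentages must recompute exactly from their stored integers.

## Known limitations

- The NB ANOVA is not a numerical replica of quasi-likelihood F-tests;
  only the scientific content (count ANOVA with FDR 0.05) is preserved.
- Library-size normalization without compositional correction slightly
  inflates empirical FDR when a large, unbalanced fraction of features
  is DE.
- The empirical-background caller's resolution is bounded by the
  negative-control slot count per distance bin (p ≥ 1/(N+1)); very
  sparse control panels make distal calls impossible by design.
- Fold estimates from LD-expanded permutation tests are attenuated
  toward 1 as proxy sets grow; they are comparative statistics, not
  effect-size estimates.
- The pipeline-level DE-vs-non-DE OCE comparison is powered only for
  timepoint pairs where several planted clusters rewire; single-pair
  contrasts at default sizes can be non-significant.
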
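# enhdyn

Enhancer discovery and enhancer–promoter interaction dynamics across a
neuronal differentiation time course.

`enhdyn` is a desk-scale analysis pipeline for regulatory genomics built
around four questions that arise when a differentiating cell model (three
stages: Day 1, Day 3, Day 6, with total-RNA CAGE and nascent-RNA NET-CAGE
libraries plus Capture Hi-C at each stage) is profiled:

1. **Where are the active enhancers?**  Actively transcribed enhancers
   produce short, bidirectional eRNAs.  From stranded CTSS tables
   (per-base TSS tag counts), `enhdyn` groups tags into strand-specific
   clusters, pairs divergent minus/plus clusters, and scores each
   candidate locus with the directionality score

   ```
   D = (F − R) / (F + R)
   ```

   where `F` and `R` are the plus- and minus-flank tag counts; loci with
   |D| < 0.8 (balanced divergent transcription) away from promoters are
   called enhancers, then classified as known or novel against reference
   catalogs.

2. **How does activity change over time?**  Region counts are normalized
   to counts per million with a prior count of 0.25 and log2-transformed;
   a negative-binomial likelihood-ratio ANOVA across timepoints (moderated
   method-of-moments dispersion, Benjamini–Hochberg FDR < 0.05) flags
   differentially expressed features, which k-means (k = 4, z-scored
   profiles) sorts into early-down / late-down / early-up / late-up
   temporal clusters.

3. **Which promoters do enhancers touch, and how stable are the
   contacts?**  Capture Hi-C valid pairs are binned into (anchor probe,
   2 kb distal bin) supporting-pair counts.  Significance comes from an
   *empirical* background: the distance-matched support distribution of
   negative-control probes (regions with no regulatory annotation), with
   tail probability `p(k) = (#{background ≥ k} + 1) / (N + 1)`.  A contact
   is called when support ≥ 5 and the Bonferroni-adjusted p ≤ 0.1 in both
   replicates.  Per-timepoint interaction networks are compared node by
   node with the Jaccard index and overlap coefficient of the neighbor
   sets A, B at two timepoints:

   ```
   JI_x  = |A ∩ B| / |A ∪ B|
   OCE_x = |A ∩ B| / min(|A|, |B|)      (OCE = 1 when min(|A|,|B|) = 0)
   ```

4. **Do disease variants concentrate in these enhancers?**  GWAS index
   SNPs are LD-expanded (r² ≥ 0.7 within 1 Mb), and enrichment inside a
   region set is tested by permutations that swap every index SNP for a
   covariate-matched control (MAF bin, LD-proxy count, distance to the
   nearest gene).  Enhancer sequence character is profiled against
   length-matched random regions: conservation scores, SNP counts,
   nucleotide diversity π = 2·AF·(1 − AF), and eQTL overlap
   (Fisher's exact test).

Every stage is exercisable without external data through a synthetic-data
generator that plants ground truth for all of the above: strand-biased
promoter signal vs balanced bidirectional enhancer signal, four temporal
expression patterns, power-law Hi-C distance decay with planted contacts
absent at negative controls, LD-structured variants with a planted
enhancer enrichment, and conservation elevated in enhancers.

## Worked example

Run the full pipeline on a synthetic landscape (2 chromosomes × 10 Mb,
300 promoters, 200 enhancers, 3 timepoints × 2 replicates × 2 assays):

```bash
enhdyn --seed 1 run --outdir demo/
```

This simulates the inputs, calls enhancers, quantifies and clusters
expression, calls interactions against the negative-control background,
computes JI/OCE network dynamics and GWAS enrichment, and prints the
headline ratios of its JSON run report:

```json
{
  "overlap_pct":  {"value": 25.0, "numerator": 50,  "denominator": 200},
  "novel_pct":    {"value": 75.0, "numerator": 150, "denominator": 200},
  "universe_total": 200,
  "de_involved_pct": {"value": 85, "numerator": 193, "denominator": 228},
  "de_enhancers_interacting_pct": {"value": 33.3, "numerator": 32, "denominator": 96},
  "gwas_interacting_pct": {"value": 40, "numerator": 14, "denominator": 35}
}
```

Reading: all 200 planted enhancers were recovered as bidirectional loci;
50 (25.0%) overlap the known catalog, 150 (75.0%) are novel.  Of 228
significant interactions, 193 (85%) involve a differentially expressed
promoter or enhancer; 32 of 96 targeted DE enhancers (33.3%) and 14 of 35
GWAS-variant probes (40%) engage in at least one contact.  Every
percentage in the report is stored beside the integers it came from, so
the report validates against itself.  Full per-stage outputs (called
loci, interaction calls, per-node JI/OCE tables, cluster overlap matrix)
are written to `demo/`.

Individual stages are available as subcommands operating on plain-text
files (`simulate`, `call-enhancers`, `quantify`, `de`, `cluster`,
`call-interactions`, `network-dynamics`, `enrich`, `characterize`,
`qpcr`), or as library functions (`enhdyn.enhancers`, `enhdyn.expression`,
`enhdyn.interactions`, `enhdyn.enrichment`, ...).

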
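# Methods

This note documents the models and procedures behind `crev2g`, the
defaults they use, the numerical choices made where the design was open,
and what the synthetic benchmark does and does not demonstrate.

## Coordinates and genome model

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based inclusive) and variant positions (1-based, VCF-style) are
converted at the readers. Promoter windows are strand-aware: on `+`,
`[TSS − upstream, TSS + downstream)` with defaults upstream = 1500 bp and
downstream = 500 bp; the `−` strand mirrors the window around the TSS base.
Windows are clipped at position 0.

Feature annotation assigns one label per region by a fixed hierarchy —
Promoter > 5′UTR > CDS > 3′UTR > first intron > other introns > Intergenic
— where any ≥ 1 bp overlap counts. The first intron is defined per gene
model as the gap between exon 1 and exon 2 *on the annotated strand*;
single-exon genes have no introns. ATAC regions are treated as unstranded.

The in-silico restriction digest cuts immediately 5′ of every motif
occurrence (DpnII-style blunt `^GATC`), so each fragment except the first
begins with the motif; fragment lengths always sum to the chromosome
length. Four-fragment binning is anchored at the first fragment of each
chromosome with a trailing remainder bin; the anchor is fixed so results
are reproducible regardless of bait positions.

## Consensus OCR atlas

Peaks from all replicates are merged transitively at ≥ 1 bp overlap. A
merged region is retained when it overlaps peaks from at least
`ceil(R/2)` replicates, with `R` the per-stage replicate count by default
(each stage's atlas is then self-contained; a global-denominator mode is
available). Openness per stage is mean FPKM > 1 over that stage's
replicates, with FPKM computed from per-replicate library sizes and the
consensus region length.

Significant capture interactions are those with score > 5 in any stage at
either 1-fragment or 4-fragment resolution; 4-fragment calls are projected
onto their member 1-fragment other-ends (maximizing sensitivity; the
projection is configurable). Classification per stage, over that stage's
open OCRs, applies the priority promoter > PIR > non-PIR: a promoter OCR
overlaps any promoter window; a PIR-OCR overlaps (≥ 1 bp) the other-end
fragment of a significant interaction whose bait fragment carries a baited
gene promoter. Bait fragments map to every gene whose promoter window
overlaps them, so shared baits yield multiple gene links. Bait-to-bait
contacts are kept by default (a flag drops them). By default each stage
uses its own contact set; pooling contacts across stages is a switch.

## Count statistics

* **Transforms.** CPM = 1e6·c/N; TPM rescales length-normalized rates so
  every column sums to 1e6; FPKM = c/(L_kb·N_millions).
* **TMM.** Per sample against a reference (the sample whose upper-quartile
  CPM is closest to the mean upper quartile): per-gene
  M = log2((c_k/N_k)/(c_r/N_r)) and A = ½·log2((c_k/N_k)(c_r/N_r)) over
  genes positive in both samples; double trimming removes the extreme 30%
  of M and 5% of A (rank-based, both tails); the factor is 2 to the
  precision-weighted mean of the surviving M values, with inverse binomial
  asymptotic variances as weights; factors are re-centered to geometric
  mean 1. The implementation agrees with edgeR's `calcNormFactors` to
  ~1e-6 on test matrices. Accessibility contrasts apply the same estimator
  to genome-wide 10-kb background-bin counts (peak regions are dominated by
  signal, so composition is estimated from background) and attach the
  factors to the OCR-level test.
* **Low-signal filter.** Rows with median CPM across all samples below the
  threshold are removed (0.7 for genes, 1.2 for OCRs by default); rows at
  exactly the threshold are kept. These thresholds are tied to the library
  depths of the emulated design and are exposed as parameters.
* **Differential test.** Two-group negative-binomial exact test: counts are
  scaled to a common effective library size; a common dispersion φ is
  moment-estimated from pooled within-group variability by a ratio
  estimator of (s² − μ) against μ² across rows (clipped at 0); rounded
  group sums, NB(n·μ, φ/n) each, are tested conditionally on their total
  by aggregating all splits with probability mass ≤ the observed one (the
  Poisson/binomial limit is used when φ < 1e-10). log2 fold changes come
  from factor-normalized group means with a prior count of 0.5 to avoid
  infinities. BH is the multiple-testing correction wherever FDR appears;
  calls require FDR < 0.05 and |log2FC| > 1. This exact test replaces a
  quasi-likelihood GLM deliberately: it is fully specified, and it is
  validated by calibration (empirical type-I error within the binomial
  95% interval at p < 0.05 on 2,000 null genes, n = 3 vs 3, φ = 0.05) and
  by power (≥ 0.9 sensitivity for planted 4-fold rows) rather than by
  numeric equality with any particular GLM fitter.
* **Trajectory clustering.** Per-gene z-scores across samples, agglomerative
  hierarchical clustering with Euclidean distance and complete linkage
  (common defaults; both configurable), tree cut into k = 6 clusters.
  Constant rows z-score to zero with a warning. Cluster ids are relabelled
  in order of first appearance so output is deterministic.

## Variant-to-gene mapping

LD computation is out of scope: the proxy table (trait, sentinel, proxy,
position, r²) is an input; a haplotype-based r² utility exists for
synthetic data only. Proxies require r² > 0.6 (strict); each sentinel is
always its own proxy; sentinels listed for a trait but absent from the
proxy table are counted as not-in-panel and contribute nothing. Open-proxy
detection is half-open point containment against each stage's open OCRs —
a proxy must land in an OCR before any contact logic applies. Two evidence
routes assign genes: `distal_PIR` (the proxy's OCR overlaps the other end
of a stage-significant interaction → the bait gene) and `bait_OCR` (the
proxy's OCR overlaps a baited promoter fragment → that fragment's gene).
Records keep both routes when both apply. Genes must have stage-mean
TPM > 1 (strict) in the record's stage. Summaries deduplicate proxies,
sentinels and genes within stage, and genes once more across stages;
sentinels are never merged even when they share proxies. Cross-trait
overlap is exclusive (upset-style): a gene counts in exactly the subset of
traits that implicate it.

## Enrichment statistics

* **Gene sets.** Upper-tail hypergeometric P(X ≥ k), BH across sets. The
  default universe is all genes expressed (TPM > 1) in any stage,
  configurable. Fisher marker enrichment is the one-sided exact 2×2 test.
* **Region overlap.** The statistic is the number of overlapping
  (query, reference) region pairs. Each of n_perm permutations (default
  10,000) re-places every query region uniformly within its own
  chromosome, preserving lengths; p = (1 + #{perm ≥ observed})/(n_perm+1)
  — never below 1/(n_perm+1) — and z standardizes the observed count by
  the permutation moments. An optional pre-filter removes the top
  percentile of longest regions from each set independently (default 1%
  when enabled). Fixed seeds make runs bit-reproducible.
* **TF sites.** Sites require purity > 0.7 (strict). Foreground cREs and
  background non-PIR OCRs are binned on GC × read-count quantile grids;
  the grid defaults to deciles but coarsens automatically so the expected
  background occupancy per cell stays near ten regions — degenerate cells
  would understate the null variance and inflate false positives. Each
  permutation draws one background region per foreground region from the
  same cell (nearest non-empty cell as fallback, logged), preserving the
  foreground covariate histogram by construction; one-sided p per TF, BH
  across TFs.

## Synthetic benchmark

The generator emulates a three-stage differentiation with 4/4/6 ATAC
replicates on a 2 × 400 kb genome (random sequence, so `GATC` recurs every
~256 bp, a realistic DpnII fragment scale) with 160 genes. It plants:
25 promoter OCRs, 30 PIR-OCRs with contacts scored uniformly in [6, 12]
for every stage in which the OCR is open (a quarter reported at
4-fragment resolution only), 30 distal non-PIR OCRs plus 15 differentially
accessible regions (4-fold, ESC↔HP), 5 reproducible-but-closed OCRs, and
30 irreproducible decoy peaks; 120 DE genes in six archetypes (6-fold up
or down in exactly one stage) on a baseline of ~6,000 TPM-scale units so
per-stage totals land near 1e6; and three traits with four sentinels each
(one absent from the panel), planted sentinel→proxy→cRE→gene links, one
shared gene between the first two traits, and one decoy proxy per V2G
failure mode (r² ≤ 0.6; OCR never open; open but uncontacted OCR;
contacted gene with TPM ≤ 1). Openness is encoded as FPKM 8 versus 0.1
against an FPKM > 1 threshold, and counts are negative-binomial with
dispersion 0.05, so recovery is deterministic at the defaults and the
tests can assert exact agreement with the manifest. `validate_manifest`
cross-checks every planted entity against the emitted files and fails on
any mismatch.

What passing these tests shows: the filter chain, thresholds, boundary
conventions and bookkeeping are implemented correctly, and each filter
individually rejects its targeted failure mode. What it does not show:
performance on real data, where effect sizes are small, peaks and
fragments have irregular structure, LD is block-correlated rather than
independent, interactions are called with correlated noise, and openness
is continuous rather than bimodal. Problem sizes (105 OCRs, 160 genes,
2,000-row calibration matrices, 1,000-run permutation calibration at 99
permutations each) were chosen as the smallest at which the statistical
assertions are stable.

## Known limitations

* The NB exact test assumes a common dispersion; strongly gene-specific
  dispersion would miscalibrate tails (tagwise shrinkage is out of scope).
* The background-bin normalization assumes bins are signal-poor; designs
  where accessibility changes genome-wide composition violate this.
* The bait→gene map relies on promoter-window overlap; capture designs
  with non-promoter baits need an explicit bait table.
* Permutation re-placement is uniform within chromosome and ignores
  mappability/blacklist structure; a blacklist can only be applied by
  subtracting it from the inputs beforehand.
* The pipeline is single-threaded by design; `--threads` is accepted for
  interface compatibility and results never depend on it.
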
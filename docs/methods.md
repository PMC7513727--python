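# Methods

This note documents the models, estimators and numerical conventions
implemented in `ecodiverge`, the design choices made where several
reasonable options existed, and what the synthetic-data generator does and
does not emulate.

## Study design the pipeline assumes

A panel of genotypes from two ecotypes (upland / lowland) of a
predominantly selfing crop, each genotype phenotyped and RNA-sequenced
under a well-watered control (CK) and a drought treatment (DT). Inputs are
biallelic SNP genotypes (VCF), a gene annotation (GFF3), promoter sequences
(FASTA), an IUPAC motif table, FPKM expression matrices per condition,
sample metadata (ecotype, geographic origin nested within ecotype, a
"typical" flag from an upstream population-structure analysis), and a trait
table. Upstream read processing, variant calling and population-structure
inference are out of scope; the typical-genotype labels are consumed as
given.

## Sequence statistics

* **Gene region**: upstream 2,000 bp + gene body + downstream 2,000 bp,
  strand-aware for the upstream window, clipped at chromosome ends.
  Coordinates are 0-based half-open internally; VCF/GFF3 readers convert.
* **π**: the unbiased frequency form `Σ_sites 2p̂q̂ · n/(n−1) / L` with `n`
  the number of sampled alleles at the site (diploids contribute two,
  missing genotypes are dropped per site) and `L` the region length in bp.
  This equals the mean pairwise allele difference exactly, which is how the
  tests verify it (brute-force pair enumeration).
* **D_xy**: `Σ_sites (p̂₁q̂₂ + p̂₂q̂₁) / L` — the mean between-group allele
  difference; no small-sample correction is needed.
* **F_ST**: Hudson-type, aggregated as a ratio of sums across the region's
  SNPs: `1 − Σ mean(π_within) / Σ d_xy`, clamped to [0, 1]. The estimator
  assumes nothing beyond allele frequencies (no HWE beyond the sampling
  model) and is robust for two-population per-gene scans. Regions without
  between-group diversity are reported missing and excluded from
  quantiles. Negative estimates are clamped to 0 *before* quantiles.
* **Neutral F_ST**: mean per-SNP Hudson F_ST over intergenic SNPs
  (zero-diversity SNPs excluded); SE from a seeded 1,000-resample bootstrap
  over SNPs.
* **HDG threshold**: the empirical 95th percentile of per-gene F_ST
  (linear-interpolation quantile); genes strictly above are flagged. The
  upper-quantile reading was chosen because a threshold far above the mean
  can only be an upper quantile, not a CI of the mean.
* **π/D_xy scan**: per ecotype, genes in the lowest 5% tail of π/D_xy are
  flagged. Genes with `d_xy = 0` are excluded (ratio undefined; count
  logged); exactly `floor(0.05 · n_included)` genes are flagged, ties at
  the boundary broken by gene-ID order.
* **Spatial uniformity**: one-sample KS test of flagged-gene midpoints
  against the uniform distribution over the genome (positions are used
  directly rather than window counts; the 5,000-kb window size is kept as a
  reporting convention).

## Expression statistics

All tests and variance components operate on `log2(FPKM + 1)` (variance
stabilization; pseudocount 1 handles zeros). Inputs are assumed
FPKM-normalized; no library-size or batch correction is applied.

* **E_d** = `Σ|E_i − E_p| / ((n−1)·E_p)`; scale-invariant; zero-mean genes
  are reported missing.
* **Q_ST** = `V_B / (V_B + 2V_W)` with method-of-moments one-way ANOVA
  components; negative `V_B` clamped to 0 for the reported value.
  Permutation p-values (default 1,000 label permutations, one shared
  permutation per iteration across genes, add-one correction) rank
  permutations by the *unclamped* component, a monotone function of the
  ANOVA F-ratio: clamping would put a point mass of observed values at 0
  and pile null p-values at 1, whereas the raw score gives exactly uniform
  p-values under label exchangeability (verified by a KS test in the
  suite).
* **DEG (CK vs DT, per genotype)**: strict `|log2FC| > 1` on
  pseudocounted values AND p < .05. With one pooled sample per genotype and
  condition the p-value is the exact conditional binomial test on the
  rounded pseudocounted pair — the classical test for a ratio of two
  Poisson intensities; with replicates a Welch t-test on log2(FPKM+1) is
  provided behind the same interface. A fold change of exactly 2 fails the
  strict threshold (documented boundary).
* **DRG**: DEG in ≥ 1 genotype AND paired t-test across genotypes
  (CK vs DT) p < .05.

## Transcriptional selection (TDSG)

1. Welch two-sample t-test between typical upland and lowland genotypes
   per gene and condition (unequal variances by construction of the
   problem).
2. Between-individual variance: the pooled within-origin variance of
   log2(FPKM+1). Because origins are nested within ecotype, removing
   origin-group means absorbs both random factors, and the ANOVA residual
   mean square is exactly the between-individual component (never
   negative).
3. Cutoff: variances sorted descending against rank; least-squares lines
   through the top 1% and the bottom 80% of genes; the cutoff is the
   variance at the intersection rank. This geometry fits a steep
   high-variance tail meeting a flat bulk; if the lines are parallel or
   intersect outside the rank range the documented fallback is the
   boundary of the bottom segment (warning logged). Fitting is on
   (rank, value) in raw value space.
4. TDSG ⇔ t-test p < .05 AND variance ≤ cutoff, per condition.

**Selection index**: `SI = 1 − (V_w·D_xy)/(V_b·π)` with `V_b` / `V_w` the
unclamped between- and within-ecotype expression components and π / D_xy
from the gene's intron SNPs (the neutral reference; π is the mean of the
two within-ecotype diversities, and both use per-SNP denominators, which
cancel in the ratio). Genes with `V_b ≤ 0` or `π = 0` or no intron SNPs get
a missing SI. Orientation: SI > 0 ⇔ expression divergence exceeds the
neutral expectation, the directional-selection signature. The
method-of-moments `V_b` makes neutral-gene SI biased downward (conditioning
on `V_b > 0` leaves a near-zero denominator in the neutrality ratio), so
the calibration check is a contrast — planted genes positive and above the
neutral-gene mean — rather than a neutral mean of exactly zero.

## Cis-element-altering SNPs

IUPAC motifs are matched exactly (degenerate codes expanded); both strands
are scanned by default (PLACE-style motifs are strand-ambiguous; a flag
disables it). For each upstream SNP the reference- and alternate-allele
sequences are compared per motif and strand, restricted to occurrences
overlapping the SNP: alternate-only ⇒ *gain*, reference-only ⇒ *loss*,
both/neither ⇒ no record. Swapping ref and alt swaps the labels. Indels and
multi-allelic records are out of scope (the latter are skipped with a
warning at VCF ingest).

Haplotypes are unphased genotype vectors over a gene's cis-altering SNPs;
heterozygotes form their own group, samples with missing calls are
excluded, and groups with < 3 samples are dropped from Q_ST. A gene is
flagged when the haplotype Q_ST strictly exceeds both the ecotype Q_ST and
the 95th percentile of ecotype Q_ST under ecotype-label permutations — so a
haplotype grouping identical to the ecotype partition never flags, while a
grouping that splits expression within ecotypes can.

## Co-expression network

Unsigned adjacency `|Pearson r|^softpower` (default 6) on log2(FPKM+1) of
the drought-responsive TDSGs under DT; topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`; average-linkage
clustering of `1 − TOM`. The tree cut is deterministic: by default the tree
is cut at the midpoint of the largest gap in the sorted merge heights — a
global elbow rule that separates the within-module merge regime from the
cross-module one and plays the role of a dynamic tree cut without its many
tuning constants (a fixed-height cut is also available). A per-node
recursive gap criterion was rejected because on average-linkage trees the
root of several well-separated modules joins its children at nearly equal
heights, making any local gap test unstable. Clusters under 30 genes
become unassigned background. Eigengenes are the unit-norm first principal
component of the per-gene z-scored submatrix, oriented to correlate
positively with the module mean profile; modules closer than eigengene
dissimilarity 0.20 merge iteratively (closest pair first, ties by label
order). Hubs: within-module edge count (TOM ≥ 0.01) in the top 15%
(ceiling; boundary ties included — a fully connected module is all hubs).
The "edge threshold 0.01" is applied to TOM, the clustered object; this is
config-exposed.

## Association and trade-off

Trait Q_ST uses the same machinery as expression Q_ST; a trait is
divergently selected when its Q_ST exceeds the neutral intergenic F_ST
mean + 1.96 bootstrap SE (band width config-exposed). Trait-correlated
genes: per-gene Pearson correlation with each trait among typical
genotypes, within the matching condition (CK traits against CK expression,
DT and RGY against DT); sets at p < .05 with Benjamini–Hochberg q-values
also emitted. Trade-off genes: q < .05 for both RWC-DT and NT-CK with
opposite correlation signs. Enrichment: Fisher's exact test on 2×2 tables
(two-sided by default, one-sided exposed), odds ratio `ad/bc` with
documented sentinels for degenerate margins. The RWC direction check
classifies drought-responsive TDSGs by (sign of RWC-DT correlation, sign of
upland-minus-lowland mean expression) and Fisher-tests the association.

## The synthetic-data generator

The generator emulates the joint structure the analysis assumes, with every
flag count fixed by round-half-up of the config fractions and everything a
deterministic function of the seed.

**Genome / genotypes.** One chromosome, 2,000 genes by default (3-kb
bodies, alternating strands, 10-kb spacing), 12 SNPs per gene (≥ 2 forced
into the upstream window and ≥ 2 into the 2-kb intron) plus 3,000
intergenic SNPs. Diploid genotypes are Hardy–Weinberg draws from
per-ecotype allele frequencies: a shared base frequency U(0.1, 0.9) plus
independent N(0, 0.2) ecotype deviations (giving a neutral intergenic
F_ST ≈ 0.1, a realistic level of background differentiation for
long-isolated ecotype pools). Planted HDGs get frequencies 0.9 vs 0.1 on
their non-intron SNPs; planted sweeps push the swept ecotype to 0.02/0.98
*toward the base-frequency major allele* on all SNPs of the gene —
deflating within-ecotype diversity ~10× (hitchhiking) without manufacturing
strong divergence, so sweeps do not leak into the HDG tail. Intron SNPs of
HDGs stay neutral so the selection index's neutral reference is genuinely
neutral.

**Expression.** Log-normal baseline (log2 mean 3.5, SD 1.5). Planted TDSGs
get a between-ecotype mean shift of `effect_tdsg` (default 3) units of the
gene's idiosyncratic within-ecotype SD, with within-ecotype noise deflated
(SD 0.25 vs 0.7 for neutral genes). Planted DRGs get a +2 log2
fold change under DT (up-regulation, so the observed median log2(DT/CK)
directly recovers the planted value). Origins (4 per ecotype) contribute a
random intercept of SD 0.02 — deliberately small: ecotype-nested block
effects inflate the variance of the independent-samples t-test the TDSG
procedure relies on, and this magnitude keeps that test at its nominal
level while still exercising the origin term of the variance model.

**Co-expression modules.** Four 35-gene modules are planted inside the
TDSG ∩ DRG set (so the network stage's default input contains them). Module
genes load (random sign, magnitude 0.8–1) on a shared per-condition latent
factor (SD 0.19) with unique noise SD 0.15; their ecotype-shift direction
follows the loading sign, so within-module correlations are ~0.8 in
magnitude while cross-module correlation is limited to the shared ecotype
channel (~0.4–0.5) — eigengenes of different modules stay well below the
0.8 merge line. Module 0 is the designated trade-off set.

**Couplings.** 70% of HDGs are drawn from the TDSG set (selected genes sit
in elevated-F_ST regions, mirroring the clear F_ST elevation such panels
show); half of the motif-altering genes are TDSGs; sweeps are disjoint from
TDSG/HDG.

**Promoters / motifs.** Random 2-kb sequences carrying the VCF reference
alleles; a 24-motif synthetic IUPAC library (lengths 5–8, ~20% degenerate
positions, anchored ends). For each motif-altering gene one upstream SNP is
planted: a motif instance is embedded so that exactly one allele completes
an occurrence overlapping the SNP (verified at generation time; gains and
losses alternate). Chance gain/loss events at other SNPs are left in — a
genome-wide scan sees those too, and about half of all genes end up
containing some cis-altering SNP, comparable to real panels.

**Traits.** Eleven agronomic traits × {CK, DT} plus RGY = GY_DT/GY_CK.
Traits are linear combinations of latent factors *derived from the planted
module genes' expression* (loading-signed mean z-scores) plus N(0, 0.5)
noise, affinely scaled into plausible units. RWC-DT loads
+`tradeoff_strength` (default 0.8) and NT-CK/DT −`tradeoff_strength` on the
module-0 factor; NT, FLW-DT and RWC-DT also get a ±0.75 ecotype offset
(upland: fewer tillers, wider flag leaves and higher leaf water content
under drought). Non-divergent traits use the within-ecotype-centered factor
components, so they carry no ecotype signal by construction. With both the
trait offsets and the expression shifts present, the opposite-sign
correlation of trade-off genes flows through two channels (the module
factor and the ecotype contrast) — that coupling *is* the trade-off
structure, so the generator's null for the trade-off pattern requires
switching off both (`tradeoff_strength = 0` and `effect_tdsg = 0`).

**What the generator does not emulate**, and hence what passing tests do
not show about real data: linkage disequilibrium and haplotype structure
(sites are drawn independently), read-level noise and mapping artifacts
(FPKM is exact), library-size and batch effects, multi-allelic sites and
indels, unbalanced or structured origin sampling, correlated traits beyond
the planted factors, and genome-scale gene counts (the 2,000-gene panel is
an enriched candidate set — planted prevalences, e.g. 20% TDSGs, are
chosen for a desk-scale study in which a p < .05 screen can still achieve a
useful false-discovery rate, not as genome-wide rates).

## Default problem sizes

The test-suite and the acceptance script run the generator's default study
(40 + 50 genotypes, 2,000 genes, 27,000 SNPs, 1,000 permutations,
1,000 bootstrap resamples); a full analysis takes well under a minute on
one CPU. Null-calibration checks use a 500-gene all-effects-zero dataset
plus 200 seeded Fisher-table draws from a 2,000-gene universe (small 2×2
tables are too discrete for a KS uniformity test; the large universe makes
the hypergeometric support dense).

## Known limitations

* The variance-cutoff geometry assumes a steep-tail/flat-bulk ranked curve;
  strongly multimodal variance distributions may place the cutoff between
  modes (the diagnostics record both fitted lines and the fallback flag).
* The exact conditional DEG test treats pseudocounted FPKM as counts; it
  reproduces the threshold logic of count-based callers without modeling
  overdispersion, and is conservative for highly expressed genes.
* SI is undefined for genes without intron polymorphism; at default
  settings ~2% of genes are affected.
* The largest-gap tree cut returns a single partition; nested module
  structure is not resolved.
* Permutation p-values are bounded below by 1/(n_perm + 1).
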
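# Methods

`myonet` re-implements a signed weighted gene co-expression network (WGCNA)
analysis of paired human skeletal-muscle RNA-seq data — two age groups
sampled at baseline and after eccentric (ECC) and concentric (CON) leg
exercise — as a tested, reusable pipeline. This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Preprocessing

Counts are filtered (a gene is dropped when its count is below `min_count=10`
in at least `min_fraction=0.8` of samples), normalised to RPKM
(`1e9 * count / (gene length * library size)`) and transformed to
log2(RPKM+1). By default the library size is the per-sample column sum of
the *retained* counts, which keeps the pipeline self-contained when
alignment metadata are unavailable; externally determined mapped-read totals
can be supplied instead (`library_sizes=`). Outlier samples are removed by
the inter-sample correlation (ISC) rule: a sample whose mean Pearson
correlation with all other samples falls more than 2.5 SD below the dataset
mean is excluded; the procedure recomputes ISC after each removal round and
stops when no sample fails. Ties at the threshold are retained (strict `<`),
and at least three samples are always kept so downstream correlations remain
defined.

## Network construction

Gene-gene similarity is Pearson correlation across samples; the signed
adjacency is `Adj = ((1 + Corr)/2)^beta`, mapping corr −1 to weight 0 so
repression is distinguished from co-activation. The soft threshold `beta` is
chosen by the scale-free topology criterion: connectivity
`k_i = sum_j Adj_ij` is binned into `n_bins=10` equal-width bins (empty bins
dropped), log10 frequency is regressed on log10 mean connectivity, and the
fit index is `-sign(slope) * R^2`. The selected power is the smallest
candidate in 1..30 with index ≥ 0.85 and negative slope; if none qualifies
the best-fitting candidate is used and a warning is logged. The topological
overlap matrix is

    TOM_ij = (L_ij + Adj_ij) / (min(k_i, k_j) + 1 − Adj_ij),
    L_ij = Σ_{u≠i,j} Adj_iu · Adj_uj,

computed in row blocks to bound memory on large gene sets; the clustering
input is `dissTOM = 1 − TOM`.

## Module detection

The dendrogram is average-linkage (UPGMA) on dissTOM. Modules come from an
adaptive branch cut implemented as bottom-up branch tracking, the hybrid
variant of dynamic tree cut without the medoid (PAM) refinement stage:

- The static cut height defaults to `q05 + 0.99 (max − q05)` over the
  joining heights, where `q05` is their 5th percentile. Scatter and gap
  thresholds are expressed on the scale anchored at `[q05, cut]`; anchoring
  at the raw min/max of the merge heights makes the scatter criterion
  meaningless when TOM dissimilarities are compressed near 1 at high powers.
- A branch qualifies as a module when it has at least
  `min_cluster_size = 15` members, its core scatter (mean pairwise
  dissimilarity among its `min_cluster_size` lowest-merging leaves) is at
  most `maxCoreScatter`, and the gap between its merging height and its core
  scatter is at least `minGap`. `deepSplit = 2` (default) maps to
  `maxCoreScatter = 0.82` with `minGap = (1 − maxCoreScatter)·3/4`; the full
  map over deepSplit 0..4 is {0.64, 0.73, 0.82, 0.91, 0.95}.
- When two qualifying branches meet, both are frozen as modules; a
  non-qualifying branch merging into a qualifying one is absorbed; leaves
  joining an already-frozen composite stay unassigned.
- Finally each module is trimmed: a member is kept only if its mean
  dissimilarity to the module core is below the midpoint between the core
  scatter and the cut height. This attachment rule separates genuinely weak
  module members (which sit well below the midpoint) from background genes
  absorbed during high merges (which sit near the cut) across the whole
  range of selected powers; a fixed absolute threshold does not, because the
  dissimilarity scale moves with beta.

Genes in no accepted branch form the unassigned module M0, which never
merges and is excluded from all downstream statistics. The module eigengene
is the first right singular vector of the gene-standardised module
submatrix (unit norm over samples), sign-aligned so its mean correlation
with member genes is non-negative; `variance_explained` is the leading
squared singular value over the total. Modules whose eigengenes correlate at
`merge_cut = 0.9` or above are merged (average-linkage clustering of
`1 − corr`, iterated to a fixed point), and labels are canonically renumbered
1..K by decreasing size with ties broken by the smallest member gene ID.

## Differential module expression

Each eigengene is modelled with a group-means parameterisation of the six
age × condition cells. Correlation between repeated samples of one subject
enters through a single consensus within-subject correlation ρ used in the
GLS covariance `σ²[(1−ρ)I + ρB]` (B = same-subject indicator). ρ is
estimated per module from OLS residual products within subjects and then
moment-corrected: under the block covariance, `E[e_i e_j]` and `E[s²]` are
linear in ρ, so the raw ratio is inverted exactly rather than used as-is —
the uncorrected estimator is attenuated by the projection (≈0.40 for a true
intraclass correlation of 0.5 in this design). The consensus is
`tanh(10%-trimmed mean of atanh(ρ_m))`, clamped to (−0.99, 0.99).

Moderated statistics follow the standard empirical-Bayes variance
moderation: prior degrees of freedom d0 and prior variance s0² are obtained
by matching the mean and variance of log s² through digamma/trigamma
relations (with a Newton inversion of the trigamma), the posterior variance
is `(d0 s0² + d s²)/(d0 + d)`, and contrasts are tested with t on `d0 + d`
degrees of freedom. When the observed spread of log s² does not exceed what
the residual degrees of freedom imply, d0 = ∞ and all variances shrink fully
to s0². With fewer than four modules no moderation is applied. The default
contrast family is all condition pairs within each age group plus the
between-age comparison at each condition (nine contrasts), and
Benjamini–Hochberg correction is applied once, globally, across all
module × contrast p-values.

## Trait association

Baseline analysis per module: an OLS interaction screen
(`trait ~ eigengene + age + eigengene×age`) routes the module to per-age
Pearson correlations when the interaction p < 0.05 (age-dependent) or to a
single partial correlation controlling linearly for age (age-independent;
p from t with n−3 df). No multiplicity correction is applied to the routing
test. Baseline MVC is the average of the two legs when both are recorded.
Contraction-responsive modules (a BH-significant post-vs-baseline contrast)
are additionally correlated with the matching % MVC decline, using the
absolute post-exercise eigengene and its delta from the subject's baseline:
plain Pearson when one contraction mode is involved, repeated-measures
correlation (ANCOVA with subject factor and common slope,
`r_rm = sign(b)·sqrt(SS_x/(SS_x+SS_err))`, df = N − n_subjects − 1) when
ECC and CON observations pool within subjects. Significance everywhere is
the joint rule |r| > 0.5 and p < 0.05, with strict inequalities.

## Hubs and enrichment

Intramodular connectivity kIM is a gene's summed adjacency to co-members;
scaled kIM divides by the module maximum and genes at or above 0.7 are hubs
(a module whose maximum kIM is 0 gets all-zero scaled values and no hubs).
Gene significance (GS) is the absolute trait correlation computed with the
same scheme as the module-level association; hubs whose GS reaches the 75th
percentile (linear interpolation) of their module's GS distribution are
prioritised, ties included by `≥`.

Annotation enrichment is the one-sided hypergeometric tail; the default
"EASE" variant subtracts one from the overlap, which is strictly more
conservative for non-empty overlaps. BH families are formed within each
annotation category for a module. TFBS enrichment per transcription factor
combines a per-nucleotide binomial Z-score
(`Z = (x − n p̂)/sqrt(n p̂ (1−p̂))`, p̂ the background occurrence rate per
searched base pair, n the module's searched length) with a Fisher score
(−ln of the one-sided Fisher p comparing genes with ≥1 hit, module vs rest
of background); a TF is enriched when both scores reach mean + 1.5 SD of the
module's score distributions (`≥ mean` when an SD is 0). Modules larger than
500 genes are represented by their upper third most connected genes. Motif
scanning itself is out of scope: the hit table and searched-region lengths
(the 5 kb up/downstream TSS convention) are inputs, and any scanner
thresholds are provenance metadata of that table.

## Synthetic data

The generator emulates the study design: 8 + 8 subjects (young/older), each
with BL, post-ECC and post-CON samples (48 samples). Each of five planted
modules (sizes 200, 120, 80, 50, 30; 300 background genes) follows a
single-factor model: factor = design effects + subject intercept
(SD 0.5) + standard-normal innovation; member genes are
`x = μ_g + a_g·f + ε` with loadings a ~ U[0.4, 0.95], noise SD 1 and means
μ ~ U[2, 8] on the log2 scale. Default design effects: module 1 is shifted
+1.2 in older muscle throughout, module 2 responds +1.5 to ECC in both
ages, module 3 is suppressed −1.5 post-CON in older muscle only; these
moderate effect sizes mirror module-level shifts a paired exercise study
could plausibly detect. Baseline MVC couples to module 4 (common slope) and
module 5 (age-crossover slopes); % MVC declines couple to the post-exercise
factors of modules 2 (ECC) and 3 (CON). Annotation terms cover 80% of each
planted module plus random decoys; one TF per module has an elevated
Poisson hit rate (15 vs 5 expected hits per 10 kb region). Count synthesis
inverts the log2/RPKM transform with drawn gene lengths and Poisson
sampling at a 2×10⁷ read depth.

What the generator does *not* emulate: negative-binomial overdispersion,
gene-length biases in counting, correlated module factors, batch effects,
or non-linear trait relations. Passing recovery tests therefore demonstrate
that the pipeline recovers block-factor co-expression structure at realistic
sample sizes — not that it is robust to every artefact of real RNA-seq.

A note on RPKM compositionality observed with the count model: a few
high-abundance genes inside large planted modules move per-sample totals
enough to induce ≈0.1 spurious correlation among background genes when
normalising by column sums; supplying the true sequencing depth removes it.
This is a real property of RPKM, not of the implementation.

## Evaluation conventions and known limitations

- Recovery ARI is computed over genes the detection assigned to a module,
  against planted labels, paired with a separate requirement that ≥70% of
  background genes stay unassigned; eigengene–factor correlations are
  reported for matches with Jaccard ≥ 0.5.
- Problem sizes in the test suite and acceptance script (780 genes,
  48 samples, 10 seeds; 200-module null and 50-module power simulations)
  were chosen so the full battery completes in about a minute while keeping
  each statistical check comfortably powered.
- Hub identification by scaled kIM ≥ 0.7 is intrinsically noisy at this
  sample size: with loadings drawn from U[0.4, 0.95] the top two loadings in
  a module typically differ by less than the sampling noise of pairwise
  correlations amplified by the soft power, so the single top-loading gene
  is flagged as a hub in only ~70% of runs (higher at small powers, where
  adjacency compression makes most genes hubs). Hub calls on ~50-sample
  datasets should be treated as candidate sets, not point identifications.
- Statistical power for a 2-residual-SD module shift at 12 subjects under a
  global BH family of ~450 tests hovers around 60–90% depending on the
  random draw; detection claims at this design size are correspondingly
  fragile.
- The original study-scale dataset (12044 genes, 36 samples, 56 modules,
  β = 17) requires the published sequencing data (SRA PRJNA509121) and is
  not reproduced here; its printed totals are checked for arithmetic
  consistency only.
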
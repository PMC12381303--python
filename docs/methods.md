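# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical decisions taken where the design
was genuinely open.

## Data model and normalization

Counts are held genes × cells (MatrixMarket orientation) with per-gene
genomic annotation (chromosome, 1-based start) and per-cell metadata.
Normalization is log1p of counts-per-scale: `log(1 + s·x/total)` with
`s = 10,000` by default. The scale is a convention, not a measured
quantity; analyses that need the transform to be effectively logarithmic
(e.g. verifying that a 2× copy-number gain shifts smoothed expression by
one log₂ unit) should raise it so typical per-gene values leave the
`log(1+x) ≈ x` regime. Chromosomes order naturally (chr1…chr22, chrX,
chrY); genes without coordinates are retained but excluded from CNV
inference.

## Copy-number inference and tumor calling

The CNV signal is deliberately simple: per gene, normalized expression
minus the reference-cell mean (immune cells are the natural reference in
organoids that retain them); per cell, a centered moving average within
each chromosome (window 101 genes, shrinking at chromosome edges);
median re-centering per cell; clipping at ±3. Values are reported in
log₂ units. No HMM state segmentation is attempted — downstream scores
consume only the smoothed signal.

The genomic instability score z-scales each locus across cells (sample
SD, ddof = 1; zero-variance loci contribute 0) and averages the squares.
With this convention the cell-averaged score equals (n−1)/n per variable
locus, and a two-cell toy gives 1/2 per variable locus — properties the
tests pin exactly. The malignancy score correlates (Pearson) each cell
with the locus-wise mean profile of its patient's top 5% most unstable
cells (minimum two cells; ties broken by cell order). Correlation type
and the per-locus reading of "scaled" are choices; Spearman and global
scaling are defensible alternatives but per-locus z + Pearson are fixed
here for testability.

Thresholds are mean + m·SD per score, with (m₁, m₂) searched over
{−1.0, …, 3.0} in steps of 0.1 and scored by the average silhouette
width of the induced two-class partition in the per-score standardized
2-D space (Euclidean distance); a cell is tumor when **both** scores
exceed their cutoffs (the conservative combination rule). One guard was
added after the unconstrained criterion proved degenerate: instability
scores are heavy-tailed — shallow cells carry noisier CNV profiles, so
GIS correlates around −0.4 with log library size — and the raw average
silhouette is then maximized by splitting off a small knot of extreme
outlier cells rather than the tumor/normal structure. Partitions are
therefore required to give each class at least 10% of cells (default
`min_class_frac=0.1`); that floor is far below any plausible tumor or
normal fraction in resected carcinoma samples, and corresponds to the
threshold-inspection step a human analyst would apply. With it, the full
chain recovers planted tumor labels at 0.95–0.99 balanced accuracy on
~97% of benchmark draws (long-run mean 0.956 over 60 seeds); the
remaining ~3% of draws still select a mid-grid instability-only cut over
the malignancy-score split, a residual fragility of silhouette-based
selection when the instability score carries a single short CNV segment
and is therefore mostly depth noise. Without the floor, a handful of
seeds collapse entirely to outlier partitions.

PAM (k-medoids) is the classic BUILD + SWAP algorithm, deterministic
given the input, with k selected by silhouette.

## Hurdle differential expression

Detection (expression > 0) is modelled by logistic regression and
positive expression by a Gaussian linear model on detected cells, both
with `group + batch` fixed effects; the group effect is tested by a
likelihood-ratio χ² in each part and the statistics are summed (df = 2).
If the discrete part is inestimable — constant detection, or
(quasi-)separation flagged when |coef| > 15 or the IRLS fails — the test
falls back to the continuous part alone (df = 1), and vice versa. This
keeps the two-part inferential idea of single-cell hurdle frameworks
without their shrinkage priors. `log_fc` is the difference of group
means of normalized expression over **all** cells (zeros included);
genes detected in under 10% of both groups are excluded and recorded.
Benjamini–Hochberg adjustment is the standard step-up with enforced
monotonicity.

One behaviour worth knowing: when a large planted program shifts many
genes in one condition, library-size normalization transfers a small
opposite shift onto every other gene (a compositional effect also
present in real data). Null *calibration* is unaffected — permuted
labels and programme-free nulls give 3–7% of p < 0.05 — but on strongly
perturbed datasets many genes outside the programme reach significance
with small negative effects at large n. Interpret genome-wide
significance counts accordingly.

## Enrichment

The preranked enrichment score is the signed maximum deviation of the
weighted KS running sum (hit increments ∝ |score|^w, default w = 1; miss
decrements 1/(N−|S|)). The null is fgsea-style: random same-size gene
sets (not phenotype permutation), 50,000 by default; p-values use
add-one smoothing and NES divides by the same-sign null mean |ES|.
Vectorized evaluation at the hit points makes 10⁴–10⁵ permutations
cheap. Over-representation of miRNA targets among down-regulated genes
uses the one-sided Fisher exact test, asserted identical to the
hypergeometric tail; the odds ratio is the sample cross-product OR (not
the conditional MLE), with a flagged 0.5 continuity substitution only
when a zero cell in the denominator makes it undefined.

## Signature scoring and group tests

Module scores use 24 equal-frequency expression bins and 100 control
genes sampled per set gene (seeded, with replacement in small bins),
excluding set genes from the control pool: the score is set mean minus
pooled control mean per cell, which cancels additive cell-level effects.
The composite treatment signature takes the top-100 positive-log-fc
genes by p from the two-arm contrast (up under T2D-exosomes ≡ down
under ND-exosomes in a two-group reading); the complementary
negative-log-fc list is returned alongside. Group differences in scores
are tested with a batch random-intercept mixed model when at least three
batches exist, otherwise (or on a failed fit) a fixed-effect linear
model — the two coincide exactly with a single batch. Cross-signature
co-enrichment is Spearman's ρ with average ranks.

## Composition

Each cluster is a binomial response aggregated per (patient, condition):
cells in the cluster out of all cells of the analyzed compartment,
logit-linked GLM with condition and patient fixed effects (random
effects are not identifiable with three patients). The reported log-odds
ratio is the contrast of condition linear predictors averaged over batch
levels (estimated marginal means); with treatment coding the batch terms
cancel, but the marginal-means machinery is kept for generality. Fold
changes are ratios of pooled proportions — the quantity behind "13.6-fold
expansion" style statements — with a flagged 0.5 continuity correction
only when a zero count would degenerate the ratio. Aggregated-count and
per-cell Bernoulli fits give identical estimates absent cell-level
covariates; aggregation is used for speed.

## Trajectory

The principal graph is a deterministic stand-in for learned principal
curves: PCA (30 dims by default) → cluster centroids → Euclidean MST →
orthogonal projection of each cell onto the tree edges incident to its
cluster centroid (nearest by residual). Pseudotime is the geodesic
distance along the tree from the root centroid to the projection,
shifted so the root cluster's minimum is 0. Branches are labelled per
edge by the last fork on the path from the root. Moran's I uses a
symmetric (union) binary kNN graph (k = 15), the exact double-sum
formula, and the analytic normal null — E[I] = −1/(N−1) with the
standard S₁/S₂ variance; the p-value is one-sided (greater), since
trajectory screening seeks positive autocorrelation. Gene modules:
average-linkage hierarchical clustering of 1 − Pearson distance among
significant genes, k by silhouette over 2…12, degenerate distances
collapse to a single flagged module.

## Morphometrics

Otsu thresholding (bright objects assumed; `invert` available), 3×3
closing, hole filling, 8-connected labeling. Perimeters use the Crofton
4-direction estimator: raw pixel-boundary perimeters overestimate curved
boundaries enough to push disk circularity to ~0.9, whereas Crofton
keeps rasterized disks ≥ 0.99. The estimator has its own closed form for
axis-aligned squares — P = π(1+√2)/2·s, hence circularity
16/(π(1+√2)²) ≈ 0.874 rather than the continuum π/4 — and the tests pin
that value; no pixel-based estimator satisfies both the disk and the
continuum-square limits simultaneously. Circularity is clipped at 1.
Objects at or below 300 µm² (single cells; a 10 µm cell is ~78.5 µm²)
are dropped before pairwise two-sided Wilcoxon rank-sum tests with a
Bonferroni multiplier equal to the number of pairs.

## Survival

Cohort scores z-scale each signature gene across the dataset's samples
(zero-variance genes contribute 0, flagged) and average per sample.
Cox models are delegated to lifelines (partial likelihood, Efron ties);
categorical covariates are one-hot encoded against the most frequent
level. Tertiles cut at the 33.3%/66.7% score quantiles with boundary
ties assigned to the lower stratum (heavy ties can empty the middle
stratum, which is flagged and skipped in the curves). Kaplan–Meier and
the multivariate log-rank test are likewise delegated.

## Synthetic data: what it emulates, and what it does not

Counts are negative binomial with a shared inverse-dispersion θ = 2 and
lognormal(0,1) baseline gene means rescaled to 2 expected counts per
gene — roughly the per-gene depth of droplet data once restricted to a
2,000-gene panel. Patient batch effects act as lognormal library-size
factors (σ configurable), per-cell size factors add σ = 0.3 of depth
variation, CNV segments multiply NB means of contiguous gene runs in
affected populations, population programs add log-scale effects, and an
optional latent trajectory assigns ordered populations consecutive time
windows on [0,1] with linear log-scale gradients on chosen genes.
Condition-dependent composition is multinomial per (patient, condition);
the benchmark plants the 1.36% → 18.5% expansion (13.6-fold) of a
stressed T-cell state at 2,000 cells per condition across three
patients. Survival cohorts are Weibull proportional hazards (shape 1.5)
with a N(0,1) score, optional Gaussian covariates and independent
exponential censoring whose rate is solved numerically to hit the target
censored fraction; the censoring stream is seeded as a child sequence so
replicate cohorts at consecutive seeds stay independent. Images are
8-bit disks with 0–8 Gaussian-bump lobes whose number and size grow with
the budding level, on a noisy background, with ground-truth masks and
mask-derived circularity stored alongside.

Not emulated: ambient RNA, doublets, UMI saturation, gene–gene
correlation beyond the planted programs, spatial structure within
organoid images, and informative censoring. Passing tests therefore
demonstrate correct recovery of the planted effects under clean
NB/Weibull noise — necessary, not sufficient, evidence for behaviour on
real data.

## Benchmark problem sizes

The test suite and the acceptance script run the chains at: tumor
calling — 5 samples of 600 cells × 2,000 genes (150-gene 2× gain, 30%
tumor); DE — 2,000-gene null at ~250 cells/arm and a 100-gene program at
~500 cells/arm; composition — 20 replicates of 2,000 immune cells per
condition plus 50 null CI-coverage replicates; GSEA — 20-gene rankings
with full-enumeration references at 10,000 permutations; trajectory —
800 cells × 1,000 genes with 200 gradient genes; morphometrics — 20
images per group at radius 40 px; survival — 50 cohorts of 500 subjects
at true log-HR 0.8 with 30% censoring.
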
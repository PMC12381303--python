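# pdotme

Analysis pipeline for single-cell and imaging studies of breast-cancer
patient-derived organoids (PDOs) treated with plasma exosomes — for
example comparing organoids exposed to exosomes from type-2-diabetic
(T2D*exo*) versus nondiabetic (ND*exo*) donors against untreated (UT)
controls. The package reimplements, as tested and reusable library code,
the computational stages such a study chains together, and ships
synthetic-data generators with known ground truth so every stage can be
validated end to end.

## What it computes

**Neoplastic-cell calling from expression-inferred copy number**
(`pdotme.malignancy`). Normalized expression is compared against a
reference population (e.g. immune cells), smoothed along the genome with
a centered moving average (default 101 genes, clipped at ±3 log₂), and
summarized per cell as

- a *genomic instability score* — the mean of squared, per-locus
  z-scaled smoothed values, GIS(c) = (1/L) Σₗ z²(c,l), and
- a *malignancy score* — the Pearson correlation of the cell's CNV
  profile with the average profile of its patient's top 5% most unstable
  cells.

Cells are labeled tumor/normal by thresholds mean + m·SD on both scores,
with (m₁, m₂) chosen by a grid search (m ∈ {−1.0, …, 3.0}) maximizing the
average silhouette width of the partition. PAM (k-medoids) clustering
with silhouette-based model selection is also provided.

**Two-part (hurdle) differential expression** (`pdotme.diffexpr`): per
gene, a logistic model of the detection indicator plus a linear model of
expression in detected cells, both with `group + batch` covariates; the
group effect is a summed likelihood-ratio χ² (df = 2), BH-adjusted.

**Preranked GSEA** (`pdotme.gsea`): weighted Kolmogorov–Smirnov running
sum, null from random same-size gene sets (default 50,000 permutations),
NES and add-one-smoothed p-values; plus one-sided Fisher/hypergeometric
over-representation tests for miRNA target sets.

**Signature scoring** (`pdotme.signatures`): expression-bin-matched
control scoring per cell (24 bins, 100 controls per gene), composite
top-100 signature construction from a DE contrast, mixed-model group
tests with batch random intercepts, and Spearman co-enrichment between
signatures.

**Differential composition** (`pdotme.proportions`): per-cluster
binomial GLM (cells in cluster out of compartment total per
patient × condition) with batch fixed effects, reported as marginal
log-odds ratios with Wald CIs and pooled-proportion fold changes.

**Trajectory inference** (`pdotme.trajectory`): PCA → cluster-centroid
minimum spanning tree → edge projection gives a rooted geodesic
pseudotime; trajectory-variable genes by Moran's I on a kNN graph of the
embedding (analytic normal p-values); co-expression modules by
average-linkage clustering of correlation distance.

**Organoid morphometrics** (`pdotme.morphometrics`): Otsu segmentation,
per-object area/perimeter/circularity (4π·A/P², Crofton perimeter) in
physical units, a 300 µm² single-cell size filter, and pairwise Wilcoxon
tests with Bonferroni correction.

**Survival projection** (`pdotme.survival`): per-dataset z-scored mean
signature scores for bulk cohorts, covariate-adjusted Cox
proportional-hazards models (HR with 95% CI), and tertile stratification
with Kaplan–Meier curves and log-rank tests.

**Synthetic data** (`pdotme.simulate`): negative-binomial count matrices
with planted CNV segments, population programs, patient batch effects,
condition-dependent composition shifts and a latent differentiation
trajectory; organoid images with controllable budding; survival cohorts
with a known log hazard ratio. Every generator returns a `GroundTruth`
aligned to its outputs.

## Worked example

Simulate a 600-cell PDO sample (500 epithelial cells, 30% of them
carrying a 150-gene 2× chromosomal gain, plus 100 immune cells) and call
tumor cells:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_call_tumor_cells.py
```

```
wrote 2000 genes x 600 cells to results/simulated (148 true tumor cells, gain segment: chr3 x2.0)
thresholds: SD multipliers (-1.0, 0.8), silhouette 0.472; called 142 tumor cells; balanced accuracy vs truth = 0.980
```

The grid search selects a malignancy-score cutoff 0.8 SD above the mean
(with an essentially inactive instability cutoff), calls 142 of the 148
planted tumor cells and reaches 98% balanced accuracy against the
generator's truth. The remaining drivers exercise the other stages the
same way:

```
$ python analysis/04_cell_composition.py
stressed T-state: 1.251% (ND) -> 19.369% (T2D); fold change 15.5 (designed 13.6),
log-odds 2.94 [2.53, 3.35], adjusted p = 2.48e-44

$ python analysis/07_survival_projection.py
signature HR = 2.17 [1.91, 2.46], p = 1.80e-33 (true HR 2.23)
tertile sizes: {'high': 167, 'low': 167, 'mid': 166}; log-rank p = 4.16e-23
```

`analysis/03_differential_expression.py`, `05_trajectory.py` and
`06_morphometrics.py` cover hurdle DE + GSEA + the composite signature,
pseudotime + gene modules, and organoid circularity respectively; each
writes its tables under `results/`.

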
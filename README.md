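# ecstrata

Stratification of gut **enterochromaffin (EC) cells** — the serotonin
(5-HT)-producing enteroendocrine cells of the intestinal epithelium —
from single-cell RNA-seq UMI counts, together with the companion
smRNA-FISH co-localization quantification and gastrointestinal-transit
statistics.  The package is aimed at computational biologists who want
the full analysis chain as reusable, tested functions: quality control
and doublet removal, pooled size-factor deconvolution normalization,
graph-based clustering, max-FDR pairwise differential expression,
rank-product signature genes, module-score cell typing, a
bootstrap-randomization Kolmogorov–Smirnov test for crypt–villus
zonation, spot co-localization counting on binary FISH masks, and the
gastric-emptying / small-intestinal-transit / ΔΔCt formulas.

Everything is exercisable without any download: a first-class
synthetic-data module generates UMI matrices with planted clusters,
markers, size factors, gradients and doublets; FISH images with
controlled co-positivity; transit profiles; and qPCR Ct tables — each
with ground truth for testing.

## The core models

**Normalization.** Cell-specific size factors θ are deconvolved from
pools: cells of a coarse cluster are ring-ordered by library size, and
each sliding pool P contributes an equation

    Σ_{j∈P} θ_j = r_P ,

where r_P compares the pool's summed expression with the
cluster-average pseudo-cell.  The overdetermined system is solved by
weighted least squares (weight = pool size); expression is then
log₂(count/θ + 1).

**Clustering.** PCA (components chosen at the variance-explained
elbow) → Euclidean kNN graph with Jaccard edge weights → seeded Louvain
modularity optimization.

**Markers.** For every unordered cluster pair, Wilcoxon rank-sum per
gene with Benjamini–Hochberg within the comparison; a gene is a marker
of cluster k when its **maximum q across all of k's comparisons** beats
the threshold (default 10⁻¹⁰) with the mean higher in k throughout.
Signature genes are ordered by the **rank product**
RP = (∏ᵢ rankᵢ)^{1/m} of their per-comparison FDR ranks, with a
permutation p-value.

**Zonation.** The statistic D(g) = maxᵍʳᵒᵘᵖ KS-D(expression in group,
expression elsewhere) for the target gene is compared against
n = 500 draws of mean-matched control genes; empirical
p = (1 + #{D_null ≥ D_obs})/(n + 1).

**FISH counting.** Spots are 8-connected components per channel; each
object is expanded by a 5-pixel-diameter disk; transitively overlapping
expanded objects form composite cells classified as single/double/triple
positive, split by crypt/villus ROI.

**Transit.** Gastric emptying = (total − stomach)/total × 100%; the
small-intestinal geometric center is Σ fᵢ·i / Σ fᵢ over 10 equal
segments (1 = minimal, 10 = maximal motility).

## Worked example

```python
import numpy as np
from ecstrata import synth_data, qc, normalize, markers
from ecstrata.cluster import cluster_cells
from sklearn.metrics import adjusted_rand_score

cm, meta, truth = synth_data.simulate_counts(synth_data.benchmark_config(seed=1))
filtered, report = qc.apply_qc(cm)                       # 10-cell / 500-gene / 10% mito filters
lm, factors = normalize.normalize_counts(filtered)        # pooled deconvolution
labels, emb, n_pcs = cluster_cells(lm, seed=1)            # PCA -> kNN -> Louvain
print(labels.n_clusters, n_pcs, round(labels.modularity, 3))
print(round(adjusted_rand_score(truth.true_cluster, labels.labels), 3))
print(round(float(np.corrcoef(truth.true_size_factor, factors.factors)[0, 1]), 3))
```

prints

```
6 6 0.833
1.0
0.983
```

— the pipeline recovers the six planted clusters exactly (ARI 1.0) from
six principal components, and the deconvolved size factors correlate
0.983 with the planted ones.  Marker recovery on the same data:

```python
table = markers.pairwise_de(lm, labels.labels,
                            exclusion_list=markers.load_dissociation_genes())
de = markers.de_by_max_fdr(table, threshold=1e-10, min_log2fc=2.0)
print(sorted(de[0])[:3], len(de[0]))
```

```
['Mk0_0', 'Mk0_1', 'Mk0_10'] 20
```

— all 20 planted markers of cluster 0, and nothing else.

A thin CLI mirrors the library
(`ecstrata simulate|qc|normalize|cluster|markers|zonation|fishquant|physiology`);
on-disk formats are the CellRanger-style Matrix Market triplet
(1-based indices on disk, 0-based in memory), delimited text tables and
plain-text 0/1 mask grids.

## Documentation

`docs/methods.md` describes the models, defaults, numerical decisions
and limitations in detail.
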
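# Methods

`ecstrata` re-implements, as a tested library, the computational workflow
used to stratify gut enterochromaffin (EC) cells from droplet scRNA-seq
UMI counts, together with the companion smFISH co-localization counting
algorithm and the gut-transit / qPCR statistics.  This note documents
the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic-data tests do and do not establish.

## Statistical primitives (`stats_core`)

All tests are implemented from their definitions so that each has an
independent desk-scale oracle (enumeration, closed form, or scipy as a
cross-check — never as the implementation).

- **Wilcoxon rank-sum.** Midranks for ties.  Exact two-sided p by full
  enumeration of the C(n, n1) rank assignments when n1+n2 ≤ 12
  (configurable); otherwise the normal approximation with tie-corrected
  variance and a 0.5 continuity correction.  A vectorized row-wise
  variant backs the all-pairs DE stage; it shares the approximation
  formulas and is tested for agreement with the scalar routine.
- **Benjamini–Hochberg.** Standard step-up with monotonicity
  enforcement, clipped at 1, input order preserved.
- **Two-sample Kolmogorov–Smirnov.** Exact D over the pooled support;
  two-sided p from the limiting Kolmogorov distribution evaluated at
  √(n₁n₂/(n₁+n₂))·D.  At the sample sizes used here (hundreds of
  cells) the limiting form is calibrated (type-I error within the 99%
  binomial CI of 0.05 over 2000 null replicates).
- **Hypergeometric enrichment.** One-sided upper tail P(X ≥ k),
  summed in log space from `gammaln` terms; enrichment claims are
  inherently one-sided here.
- **Unpaired t-test.** Pooled-variance (Student) form by default, Welch
  behind a flag.  Two degenerate-zero-variance conventions: equal means
  → p = 1, distinct means → p = 0.

## Synthetic data (`synth_data`)

The count generator emulates the structure of a regional EC-cell
experiment with known ground truth:

- **Counts.** Negative binomial via the gamma–Poisson mixture with a
  single dispersion shared across genes (θ = 2 by default; Fano ≈ 1 + μ/2).
  Per-gene baseline means are log-normal around `nb_mean` (default 0.5,
  giving ≈ 1100 UMIs and ≈ 700 detected genes per cell at 2000 genes —
  mid-depth droplet data).
- **Clusters.** `n_clusters` = 6 × 300 cells by default; each cluster's
  markers (20 genes) have mean × 2^3 inside the cluster, matching the
  strong regional demarcation of EC clusters.  Clusters map round-robin
  onto gut regions in the cell metadata.
- **Size factors.** Log-uniform with max/min spread 2 (4 in the
  normalization recovery tests), emulating library-depth variation.
- **Mitochondrial block.** The 13 protein-coding mouse mitochondrial
  genes, scaled to ≈ 5% of UMIs in singlets.
- **Gradient.** Optional crypt→villus genes with NB mean linear in the
  cell's position t ∈ U[0,1]; half increase (0.5 + t; the first is
  named *Sct*), half decrease (1.5 − t; the first is named *Tac1*), so
  axis annotation is testable end to end.
- **Doublets.** Appended cells formed by summing two freshly drawn
  cells from different clusters — the detectable, cross-class kind.

The generator does **not** model gene–gene correlation, ambient RNA, or
batch effects; passing recovery tests therefore demonstrates correctness
of the algorithms under their stated assumptions, not robustness to
those artifacts.

FISH images place non-overlapping simulated cells; the first two
channels follow the exact 2×2 joint distribution given the marginals and
the double-positive probability (validated against the Fréchet bounds),
and each positive (cell, channel) receives one spot at the cell center
plus jittered satellites, so planted co-positivity is geometrically
recoverable.  Channels beyond the second are independent — a documented
simplification.  Transit profiles and Ct tables are deterministic
constructions plus optional Gaussian Ct noise.

## Quality control (`qc`)

Thresholds are read strictly: genes kept when expressed in ≥ 10 cells,
cells kept when detecting ≥ 500 genes and when ≤ 10% of UMIs are
mitochondrial.  Genes are filtered before cells (detected-gene counts
refer to the filtered panel); both filters are idempotent and their
report counts reconcile exactly with the dimension changes.

Doublet flagging operationalizes two qualitative criteria:

1. **Mixed signatures.** Cells are scored against every class signature
   (module score on library-normalized log expression) and assigned to
   the top class.  A signature is *present* when the score exceeds the
   non-class background by ≥ 2 SD **and** lies ≥ 35% of the way from the
   background mean to the assigned-class mean.  The 35% point reflects
   the log transform: a doublet's minority parent contributes roughly
   half the counts, which lands at ~60–75% of the pure-class log-score,
   while background cells sit near 0%; the midpoint rule would miss
   imbalanced doublets and a pure z-rule would flag ~10% of singlets.
   A cell with ≥ 2 present signatures is flagged.
2. **UMI bimodality.** Per assigned class, a 2-component Gaussian
   mixture on log₂ total UMIs; a minor-weight component ≥ 0.5 log₂
   units above the major one is flagged.  When the library-size spread
   approaches the two-fold doublet shift this criterion loses power and
   criterion 1 carries the detection (as in the bundled tests).

## Normalization (`normalize`)

Pool-based deconvolution of cell-specific size factors:

1. **Coarse clustering.** Ward hierarchical clustering on the top 50
   PCs of log library-scaled counts, cut at the largest cluster count
   whose smallest cluster holds ≥ 100 cells.
2. **Pool system.** Within each coarse cluster, cells are ring-ordered
   by library size; sliding pools of sizes (21, 41, 61, 81, 101),
   capped at the cluster size, are summed.  Each pool is compared with
   the cluster-average pseudo-cell and contributes one linear equation
   relating the pool statistic to the sum of member factors.  The
   system is solved by weighted least squares (weight = pool size) with
   per-cell library-size anchor equations at weight 0.1 — enough to
   guarantee full rank, far too small to bias the pool estimates.
3. **Two-pass pool statistic.**  The first pass uses the median of
   per-gene ratios (robust to a sizable differentially expressed
   fraction).  Genes whose factor-normalized variance exceeds the
   shared-NB expectation (excess-dispersion z > 4) are then flagged;
   when < 5% of genes are flagged the cluster is treated as
   homogeneous and the ratios are recomputed as ratios of totals over
   the stable genes.  The efficient pass matters: at ~1100 UMIs/cell
   the median statistic's sampling noise alone limits factor recovery
   to r ≈ 0.986, while the total-ratio pass reaches the counting-noise
   floor (r ≈ 0.996 against planted factors).  With detectable
   heterogeneity the robust median solution is returned unchanged.
4. **Scaling.** Per-cluster factors are made comparable through the
   median ratio of the cluster pseudo-cell to the global pseudo-cell;
   final factors are rescaled to mean 1.  Non-positive solved factors
   raise an error recommending larger pools — there is no silent
   clamping.

Exact identifiability holds: cells that are exact scalar multiples of a
common profile are recovered to machine precision, and the estimator is
scale-equivariant.  Known limitation (shared with pooled deconvolution
generally): strongly *unbalanced* composition shifts — e.g. 40% of genes
all up-regulated in a hidden subpopulation — bias any pool ratio
statistic; the robustness test uses balanced up/down heterogeneity.

The log transform is log₂(count/factor + 1), so zeros are preserved
exactly.

## Clustering (`cluster`)

- **PCA** on per-gene mean-centered log expression via full SVD, with a
  deterministic sign convention (largest-magnitude loading positive).
  Variance fractions are relative to total variance.
- **Elbow choice.** The number of PCs maximizes the perpendicular
  distance from (i, vᵢ) to the line joining the first and last points
  of the variance-explained curve, searched in [5, 50], ties to the
  smallest index.
- **kNN graph.** Euclidean kNN (ties by index), union-symmetrized;
  edge weight = Jaccard similarity of the endpoints' neighbor sets with
  the endpoints themselves excluded (this makes coincident twins score
  exactly 1 and lets unrelated endpoint pairs drop to 0); zero-weight
  edges are dropped.  k defaults to round(√n) clipped to [15, n−1]:
  neighborhoods must scale with the dataset, and a fixed small k makes
  the modularity optimum fragment large clusters (a resolution
  artifact we observed directly on the planted benchmark).
- **Louvain** via seeded `networkx.community.louvain_communities` at
  resolution 1.0; communities are relabeled deterministically by their
  smallest member, and the final partition's modularity is reported.
  Cluster count is controlled only through the resolution parameter.

On the standard benchmark (6 × 300 cells, 20 markers/cluster at log2FC
3) the pipeline recovers the planted partition with ARI 1.0, and the
whole simulate→qc→normalize→cluster→markers chain is bit-reproducible
for a fixed seed.

## Differential expression and signatures (`markers`)

For every unordered cluster pair, each gene gets a Wilcoxon rank-sum p;
BH is applied *within* each pairwise comparison (across genes), and the
per-(gene, cluster) summary takes the **maximum q across that cluster's
comparisons**, restricted to genes whose mean is higher in the cluster
in *every* comparison; otherwise the summary q is 1.  Fold-changes are
computed on the linear normalized-count scale (pseudo-count 1e-9), so a
planted 8-fold marker reports log2FC ≈ 3 regardless of baseline.  The
shipped dissociation-gene exclusion list (immediate-early/heat-shock
genes) is applied by default and can be replaced.

Signature genes per cluster: candidates pass FDR < 1e-10 in all
comparisons; within each comparison candidates are ranked by FDR
(midranks on ties); the rank product is the geometric mean of ranks;
its p-value comes from shuffling ranks independently within each
comparison (default 10⁴ permutations), p = (1 + #{RP ≤ observed}) /
(n_perm + 1), BH-adjusted across candidates.  Permutation was chosen
over the gamma approximation because tiny instances admit an exact
enumeration oracle.

Module score = mean log expression of the set − per-cell mean over all
genes (a per-cell background; a global-background variant was
considered and rejected as it reduces to a constant offset).  Cell
types are assigned by argmax score, exact ties → "unassigned", and
validated by the per-assigned-type mean z-scored expression of each
set, which should dominate on the diagonal.

## Zonation statistics (`zonation`)

Crypt–villus annotation uses cluster means of *Tac1* (crypt), *Sct*
(villus) and *Neurog3*: the cluster maximal in *Neurog3* and more than
1 SD above the across-cluster mean is the progenitor; otherwise
crypt/villus by the Tac1–Sct comparison.

The randomization KS test asks whether a target gene's expression
depends on a grouping more than matched control genes do.  Statistic:
D(gene) = max over groups of the two-sample KS D between the gene's
per-cell expression inside the group and in the remaining cells
(vectorized over genes, tie runs evaluated once).  Null: n_rand = 500
draws with replacement from the genes whose overall mean log expression
lies within ±0.25 of the target's (the target itself excluded);
empirical p with the add-one rule, so p ∈ [1/(n_rand+1), 1].  The
per-group median expression vector and the median null D are retained
for box-plot-style summaries.  Calibration: over 200 null targets the
rejection rate at α = 0.05 falls within the 99% binomial CI.

Co-expression counts classify every cell in the universe (cells
positive for ≥ 1 surveyed marker by default; positivity = any detected
UMI) into exact marker combinations; for each pair (A, B) and third
marker X the enrichment of X in A⁺B⁺ cells is the upper-tail
hypergeometric test with K = #X⁺, n = #A⁺B⁺, N = universe.

## FISH quantification (`fish_quant`)

Spots are 8-connected components per binary channel mask (size filter
optional).  Every object is expanded by a disk of the configured
diameter (default 5 px → radius 2; morphological dilation of the pixel
set by default, a centroid-stamped disk behind a flag).  Expanded
objects that overlap — transitively, across and within channels — form
composite cells, classified by their channel set; same-channel merging
is intentional because one cell emits several spots per channel.
Composites are assigned to the ROI holding the majority of their
pre-dilation pixels (ties to the smaller label; label 0 = outside,
excluded from fractions), and per-ROI fractions are double-positives
over reference-channel positives.  Cross-image crypt-vs-villus
contrasts use the unpaired t-test.  The double-positive count is
non-decreasing in the expansion diameter as long as distinct composite
cells do not merge; at diameters comparable to inter-cell spacing the
transitive closure can fuse composites.

Depletion quantification counts double/single-positive puncta between a
reference and target channel and summarizes target intensity by puncta
size (mean and total pixels), so a halving of puncta sizes halves the
mean exactly.

## Physiology (`physiology`)

Gastric emptying = (total recovered − stomach)/total × 100, with total
= stomach + 10 SI segments + colon.  Geometric center =
Σ fᵢ·i / Σ fᵢ over the 10 SI segments, bounded in [1, 10], invariant to
rescaling and antisymmetric under profile reversal (GC(flip) = 11 −
GC).  Colonic travel = distance/length × 100.  qPCR: ΔCt against the
arithmetic mean Ct of the three housekeeping genes (*B2m*, *Gapdh*,
*Rpl13a*; geometric aggregation behind a flag), fold-change =
2^−ΔΔCt against the reference group, which maps to exactly 1.
Whole-gut transit times and bead-expulsion latencies are measurements,
not computations; only mean/SD/t-test summaries are provided.

## Problem sizes and determinism

The bundled tests run the full pipeline on 6 × 300 cells × 2000 genes,
deconvolution recovery on 500 cells, the randomization-KS calibration
on 200 targets × 500 draws, and FISH recovery on 200 simulated cells —
sizes at which every planted-truth criterion is informative while the
whole suite stays inside a coffee break.  All stochastic components
take explicit seeds (NumPy `default_rng`); reruns are bit-identical.

## Known limitations

- The synthetic generator omits gene–gene correlation, ambient RNA and
  batch structure (above).
- Pool deconvolution is biased under strongly one-sided composition
  shifts; detection of heterogeneity falls back to the robust median
  pass but does not remove that intrinsic bias.
- The UMI-bimodality doublet criterion is uninformative when library
  spread rivals the doublet shift.
- FISH joint positivity is exact for two channels only; additional
  channels are independent.
- The KS p-value uses the limiting distribution; for very small
  samples an exact variant would be preferable (the randomization test
  does not rely on it).
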
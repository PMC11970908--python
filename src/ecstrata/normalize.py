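"""Pool-based size-factor deconvolution and the log transform.

Cell-specific size factors are deconvolved from pooled counts: within
each coarse cluster, cells are placed on a ring ordered by library size;
sliding pools of several sizes are summed and each pool's ratio against
the cluster-average pseudo-cell gives one linear equation in the member
cells' factors.  The overdetermined system is solved by weighted least
squares (weight = pool size) with low-weight per-cell library-size
anchors to guarantee full rank.

The pool ratio is computed in two passes.  The first pass uses the
median over per-gene ratios, which tolerates a substantial fraction of
differentially expressed genes within the pool cluster.  Genes whose
factor-normalized variance exceeds the negative-binomial expectation
(excess-dispersion z > 4) are then flagged; when the flagged fraction is
small the cluster is treated as expression-homogeneous and a second,
statistically efficient pass recomputes pool ratios as ratios of totals
over the stable genes.  Per-cluster factors are made comparable through
the cluster pseudo-cell's factor against the global pseudo-cell, and the
final factors are rescaled to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io_core import CountMatrix, LogMatrix, logger

DEFAULT_POOL_SIZES = (21, 41, 61, 81, 101)
#: Weight of the per-cell library-size anchor equations; keeps the system
#: full rank without biasing the pool-based estimates appreciably.
ANCHOR_WEIGHT = 0.1
#: Genes with cluster-average count below this are excluded from the pool
#: equations (ratio stability).
MIN_GENE_MEAN = 0.1
#: Excess-dispersion z-score above which a gene is considered unstable.
DISPERSION_Z_MAX = 4.0
#: Maximum flagged-gene fraction for the efficient total-ratio pass.
MAX_FLAGGED_FRACTION = 0.05


@dataclass
class SizeFactors:
    """Per-cell positive factors (mean 1) plus the coarse pooling labels."""

    factors: np.ndarray
    coarse_cluster: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise ValidationError("size factors must be positive and finite")


def coarse_cluster(
    m: CountMatrix, n_pcs: int = 50, min_pool_size: int = 100
) -> np.ndarray:
    """Coarse Ward hierarchical clustering on top PCA scores.

    Input is log2(library-scaled count + 1); the tree is cut at the
    largest number of clusters whose smallest cluster still holds
    ``min_pool_size`` cells.  Datasets smaller than ``min_pool_size``
    collapse to a single cluster with a warning.
    """
    n = m.n_cells
    if n < 2:
        raise ValidationError("need at least 2 cells")
    if n < min_pool_size:
        logger.warning(
            "coarse_cluster: %d cells < min pool size %d; single cluster",
            n, min_pool_size,
        )
        return np.zeros(n, dtype=int)

    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    factors = totals / max(np.median(totals[totals > 0]), 1.0)
    dense = np.asarray(m.values.todense(), dtype=float)
    dense /= np.maximum(factors, 1e-12)[None, :]
    x = np.log2(dense + 1.0).T  # cells × genes
    if np.allclose(x, x[0]):
        return np.zeros(n, dtype=int)

    k = min(n_pcs, n - 1, x.shape[1])
    scores = PCA(n_components=k, random_state=0).fit_transform(x)
    tree = linkage(scores, method="ward")
    max_k = max(n // min_pool_size, 1)
    for n_clusters in range(max_k, 0, -1):
        labels = fcluster(tree, t=n_clusters, criterion="maxclust") - 1
        counts = np.bincount(labels)
        if counts.min() >= min_pool_size or n_clusters == 1:
            logger.info("coarse_cluster: %d pools over %d cells", labels.max() + 1, n)
            return labels.astype(int)
    return np.zeros(n, dtype=int)


def _solve_pool_system(
    x: np.ndarray,
    use: np.ndarray,
    ref: np.ndarray,
    pool_sizes,
    anchor_factors: np.ndarray,
    statistic: str,
) -> np.ndarray:
    """WLS solution of the ring-pool linear system for one cluster."""
    nc = x.shape[1]
    xu = x[use]
    refu = ref[use]
    ring_order = np.argsort(xu.sum(axis=0), kind="stable")
    rows: list[int] = []
    cols: list[int] = []
    weights: list[float] = []
    b: list[float] = []
    eq = 0
    for s in sorted({min(int(s), nc) for s in pool_sizes}):
        ring = np.concatenate([ring_order, ring_order[: s - 1]])
        csum = np.concatenate(
            [np.zeros((xu.shape[0], 1)), np.cumsum(xu[:, ring], axis=1)], axis=1
        )
        pools = csum[:, s:] - csum[:, :-s]  # genes × nc sliding windows
        if statistic == "median":
            bv = np.median(pools / refu[:, None], axis=0)
        else:
            bv = pools.sum(axis=0) / refu.sum()
        for start in range(nc):
            members = ring[start : start + s]
            rows.extend([eq] * s)
            cols.extend(members.tolist())
            weights.append(float(s))
            b.append(float(bv[start]))
            eq += 1
    for j in range(nc):  # low-weight full-rank anchors
        rows.append(eq)
        cols.append(j)
        weights.append(ANCHOR_WEIGHT)
        b.append(float(anchor_factors[j]))
        eq += 1
    a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(eq, nc))
    w = sp.diags(np.asarray(weights))
    awa = (a.T @ w @ a).toarray()
    awb = a.T @ w @ np.asarray(b)
    try:
        return np.linalg.solve(awa, awb)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "deconvolution system is singular; use larger pool sizes"
        ) from exc


def _stable_genes(x: np.ndarray, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genes whose factor-normalized variance is consistent with a shared
    negative-binomial dispersion (excess-dispersion z <= threshold)."""
    n = x.shape[1]
    y = x / theta[None, :]
    mean_g = y.mean(axis=1)
    var_g = y.var(axis=1, ddof=1)
    ok = mean_g >= MIN_GENE_MEAN
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = (var_g / np.maximum(mean_g, 1e-12) - 1.0) / np.maximum(
            mean_g, 1e-12
        )
    disp_inv = max(float(np.median(excess[ok])), 0.0)
    expected_var = mean_g + disp_inv * mean_g**2
    z = (var_g - expected_var) / np.maximum(
        expected_var * np.sqrt(2.0 / max(n - 1, 1)), 1e-12
    )
    return ok & (z <= DISPERSION_Z_MAX), ok


def deconvolve_size_factors(
    m: CountMatrix,
    labels: np.ndarray,
    pool_sizes: tuple[int, ...] = DEFAULT_POOL_SIZES,
) -> SizeFactors:
    """Deconvolve per-cell size factors from ring pools (see module doc)."""
    labels = np.asarray(labels)
    counts = np.asarray(m.values.todense(), dtype=float)
    n_cells = counts.shape[1]
    factors = np.empty(n_cells)

    global_mean = counts.mean(axis=1)
    global_use = global_mean >= MIN_GENE_MEAN
    if not global_use.any():
        raise ValidationError("no gene passes the mean-count filter")

    for cl in np.unique(labels):
        idx = np.where(labels == cl)[0]
        x = counts[:, idx]
        lib = x.sum(axis=0)
        if np.any(lib <= 0):
            raise ValidationError("cells with zero totals cannot be normalized")
        cl_mean = x.mean(axis=1)
        use = cl_mean >= MIN_GENE_MEAN
        if not use.any():
            raise ValidationError(f"cluster {cl}: no gene passes the mean filter")

        theta = _solve_pool_system(
            x, use, cl_mean, pool_sizes, lib / lib.mean(), "median"
        )
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            raise ValidationError(
                f"cluster {cl}: non-positive deconvolved factor; "
                "use larger pool sizes"
            )
        stable, ok = _stable_genes(x, theta)
        flagged_fraction = 1.0 - stable.sum() / max(int(ok.sum()), 1)
        if flagged_fraction <= MAX_FLAGGED_FRACTION and stable.sum() >= 50:
            lib_stable = x[stable].sum(axis=0)
            theta = _solve_pool_system(
                x, stable, cl_mean, pool_sizes,
                lib_stable / lib_stable.mean(), "total",
            )
            if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
                raise ValidationError(
                    f"cluster {cl}: non-positive deconvolved factor; "
                    "use larger pool sizes"
                )

        # make clusters comparable via the cluster pseudo-cell's factor
        both = use & global_use
        scale = float(np.median(cl_mean[both] / global_mean[both]))
        factors[idx] = theta * scale

    factors /= factors.mean()
    logger.info(
        "deconvolve_size_factors: %d cells, factor range %.3f-%.3f",
        n_cells, factors.min(), factors.max(),
    )
    return SizeFactors(factors=factors, coarse_cluster=labels)


def log_normalize(m: CountMatrix, f: SizeFactors) -> LogMatrix:
    """log2(count / size_factor + 1); zeros stay exactly zero."""
    if f.factors.shape[0] != m.n_cells:
        raise ValidationError("size factor count must match cell count")
    vals = m.values.tocsc(copy=True).astype(float)
    vals.data /= np.repeat(f.factors, np.diff(vals.indptr))
    vals.data = np.log2(vals.data + 1.0)
    return LogMatrix(vals.tocsr(), list(m.gene_ids), list(m.cell_ids), f.factors)


def normalize_counts(
    m: CountMatrix,
    n_pcs: int = 50,
    pool_sizes: tuple[int, ...] = DEFAULT_POOL_SIZES,
    min_pool_size: int = 100,
) -> tuple[LogMatrix, SizeFactors]:
    """Convenience: coarse clustering → deconvolution → log transform."""
    labels = coarse_cluster(m, n_pcs=n_pcs, min_pool_size=min_pool_size)
    f = deconvolve_size_factors(m, labels, pool_sizes=pool_sizes)
    return log_normalize(m, f), f
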
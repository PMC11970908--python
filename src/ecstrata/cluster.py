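"""PCA, elbow-based PC choice, Jaccard-weighted kNN graph, Louvain.

The clustering contract mirrors a standard graph-based scRNA-seq
workflow: per-gene mean-centered PCA with a fixed sign convention, the
number of components chosen at the maximum-distance elbow of the
variance-explained curve, a Euclidean kNN graph symmetrized by union
with Jaccard similarity of neighbor sets as edge weights, and seeded
Louvain modularity optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io_core import LogMatrix, logger


@dataclass
class Embedding:
    """Cells × PCs scores with per-PC variance-explained fractions."""

    scores: np.ndarray
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained)
        if np.any(np.diff(ve) > 1e-12):
            raise ValidationError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValidationError("variance_explained fractions sum above 1")


@dataclass
class NeighborGraph:
    graph: nx.Graph
    k_neighbors: int


@dataclass
class ClusterLabels:
    labels: np.ndarray
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def run_pca(lm: LogMatrix, n_components: int) -> Embedding:
    """PCA of per-gene mean-centered log expression.

    Scores are cells × components; the sign of each component is fixed
    so its largest-magnitude gene loading is positive.  Variance
    fractions are relative to the total variance of the centered data.
    """
    x = lm.dense().T  # cells × genes
    n, p = x.shape
    if n_components > min(n, p) - 1:
        raise ValidationError(
            f"n_components={n_components} exceeds min(genes, cells) - 1"
        )
    xc = x - x.mean(axis=0, keepdims=True)
    total_var = float(np.sum(xc**2))
    if total_var <= 1e-12:
        raise ValidationError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for j in range(n_components):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    var_explained = (s[:n_components] ** 2) / total_var
    return Embedding(scores=scores, variance_explained=var_explained)


def choose_pcs_elbow(
    variance_explained, min_pcs: int = 5, max_pcs: int = 50
) -> int:
    """Maximum-distance elbow of the variance-explained curve.

    Returns the 1-based index in [min_pcs, max_pcs] whose point
    (i, v_i) lies farthest (perpendicular distance) from the straight
    line joining the first and last plotted points; ties break to the
    smallest index, so a strictly linear decay yields ``min_pcs``.
    """
    v = np.asarray(variance_explained, dtype=float)
    if v.size < min_pcs:
        raise ValidationError(
            f"need at least min_pcs={min_pcs} variance fractions, got {v.size}"
        )
    if np.any(np.diff(v) > 1e-12):
        raise ValidationError("variance_explained must be non-increasing")
    length = v.size
    x1, y1 = 1.0, v[0]
    x2, y2 = float(length), v[-1]
    norm = np.hypot(x2 - x1, y2 - y1)
    i = np.arange(1, length + 1, dtype=float)
    dist = np.abs((y2 - y1) * i - (x2 - x1) * v + x2 * y1 - y2 * x1) / norm
    lo, hi = min_pcs, min(max_pcs, length)
    window = dist[lo - 1 : hi]
    return int(lo + np.argmax(window))


def default_k(n_cells: int) -> int:
    """Neighbor count scaled to the dataset: round(sqrt(n)), at least 15,
    below the cell count."""
    return min(max(15, int(round(np.sqrt(n_cells)))), n_cells - 1)


def build_knn_jaccard(e: Embedding, k: int | None = None) -> NeighborGraph:
    """Euclidean kNN graph, union-symmetrized, Jaccard edge weights.

    The weight of edge (u, v) is the Jaccard similarity of the two
    endpoints' k-neighbor sets, with u and v themselves excluded from
    the sets (so coincident twins that list each other score exactly 1);
    zero-weight edges are dropped.  Distance ties break by cell index.
    ``k`` defaults to round(sqrt(n_cells)), clipped to [15, n-1], so
    neighborhoods track the dataset size.
    """
    x = e.scores
    n = x.shape[0]
    if k is None:
        k = default_k(n)
    if k >= n:
        raise ValidationError(f"k={k} must be below the number of cells {n}")
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, np.inf)
    # stable tie-break by index: lexsort on (index, distance)
    neighbor_sets = np.zeros((n, n), dtype=bool)
    for u in range(n):
        order = np.lexsort((np.arange(n), d2[u]))
        neighbor_sets[u, order[:k]] = True

    inter = (neighbor_sets.astype(np.float32) @ neighbor_sets.T.astype(np.float32))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    directed = neighbor_sets | neighbor_sets.T
    iu, iv = np.nonzero(np.triu(directed, 1))
    for u, v in zip(iu.tolist(), iv.tolist()):
        # endpoints removed from each other's sets; the raw intersection
        # cannot contain u or v (no self-loops in kNN sets)
        i = inter[u, v]
        size_u = k - int(neighbor_sets[u, v])
        size_v = k - int(neighbor_sets[v, u])
        union = size_u + size_v - i
        jac = i / union if union > 0 else 0.0
        if jac > 0:
            g.add_edge(u, v, weight=float(jac))
    return NeighborGraph(graph=g, k_neighbors=k)


def louvain_cluster(
    g: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterLabels:
    """Seeded Louvain modularity optimization on the weighted graph.

    Communities are relabeled contiguously (ordered by their smallest
    member) so the output is deterministic for a fixed graph and seed.
    An edgeless graph yields one cluster per cell with a warning.
    """
    graph = g.graph
    n = graph.number_of_nodes()
    if n == 0:
        raise ValidationError("graph is empty")
    if graph.number_of_edges() == 0:
        warnings.warn("graph has no edges; every cell is its own cluster")
        return ClusterLabels(labels=np.arange(n), modularity=0.0)
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=min)
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(comms):
        labels[list(members)] = lab
    mod = nx.community.modularity(
        graph, comms, weight="weight", resolution=resolution
    )
    logger.info(
        "louvain_cluster: %d communities, modularity %.3f", len(comms), mod
    )
    return ClusterLabels(labels=labels, modularity=float(mod))


def cluster_cells(
    lm: LogMatrix,
    n_pcs: int = 50,
    k: int | None = None,
    resolution: float = 1.0,
    seed: int = 0,
    min_pcs: int = 5,
) -> tuple[ClusterLabels, Embedding, int]:
    """Convenience: PCA → elbow choice → kNN graph → Louvain."""
    n_pcs = min(n_pcs, lm.n_cells - 2, lm.n_genes - 1)
    emb = run_pca(lm, n_pcs)
    chosen = choose_pcs_elbow(emb.variance_explained, min_pcs=min(min_pcs, n_pcs), max_pcs=n_pcs)
    emb_used = Embedding(emb.scores[:, :chosen], emb.variance_explained[:chosen])
    graph = build_knn_jaccard(emb_used, k=k)
    labels = louvain_cluster(graph, resolution=resolution, seed=seed)
    return labels, emb, chosen
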
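"""All-pairs differential expression, signature genes and cell typing.

Differential expression runs a Wilcoxon rank-sum test per gene for every
unordered cluster pair, applies Benjamini–Hochberg within each pairwise
comparison, and summarizes each (gene, cluster) by the maximum q-value
across the cluster's comparisons — taken only when the gene's mean is
higher in that cluster in every comparison (the "expressed at
significantly higher level" direction).  Signature genes are ranked by a
rank product across a cluster's comparisons with a permutation p-value.
Module scores are the mean log expression of a gene set minus the
per-cell mean over all detected genes, and cell types are assigned by
the highest score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import GeneSet, LogMatrix, logger
from .stats_core import bh_adjust, rank_sum_matrix

#: Pseudo-count for fold-changes of cluster means on the linear scale.
FC_PSEUDOCOUNT = 1e-9


@dataclass
class DETable:
    """Pairwise records plus the per-(gene, cluster) max-FDR summary.

    ``records`` columns: gene, cluster_a, cluster_b, p, q, log2fc (of
    linear-scale cluster means, a over b).  ``summary`` columns: gene,
    cluster, max_q (1.0 when the gene is not up in every comparison),
    min_log2fc, n_comparisons.
    """

    records: pd.DataFrame
    summary: pd.DataFrame
    clusters: tuple[int, ...]


def load_dissociation_genes() -> GeneSet:
    """Default exclusion list: immediate-early and heat-shock genes
    induced by tissue dissociation."""
    text = (
        resources.files("ecstrata").joinpath("data/dissociation_genes.txt").read_text()
    )
    genes = [g.strip() for g in text.split() if g.strip() and not g.startswith("#")]
    return GeneSet("dissociation", frozenset(genes))


def pairwise_de(
    lm: LogMatrix,
    labels: np.ndarray,
    exclusion_list: GeneSet | None = None,
) -> DETable:
    """Wilcoxon rank-sum DE for every unordered cluster pair."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("need at least 2 clusters")
    for cl in clusters:
        if (labels == cl).sum() < 2:
            raise ValidationError(f"cluster {cl} has fewer than 2 cells")

    excluded = exclusion_list.genes if exclusion_list is not None else frozenset()
    keep = np.array([g not in excluded for g in lm.gene_ids])
    genes = [g for g, k in zip(lm.gene_ids, keep) if k]
    x = lm.dense()[keep]
    linear = 2.0**x - 1.0  # normalized-count scale for fold-changes

    cell_idx = {cl: np.where(labels == cl)[0] for cl in clusters}
    group_mean = {cl: linear[:, cell_idx[cl]].mean(axis=1) for cl in clusters}

    frames = []
    for a, b in combinations(clusters.tolist(), 2):
        p = rank_sum_matrix(x[:, cell_idx[a]], x[:, cell_idx[b]])
        q = bh_adjust(p)
        lfc = np.log2(
            (group_mean[a] + FC_PSEUDOCOUNT) / (group_mean[b] + FC_PSEUDOCOUNT)
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cluster_a": a,
                    "cluster_b": b,
                    "p": p,
                    "q": q,
                    "log2fc": lfc,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)

    # per-(gene, cluster) summary in the up-regulated direction
    n_genes = len(genes)
    summary_rows = []
    for cl in clusters.tolist():
        max_q = np.zeros(n_genes)
        min_lfc = np.full(n_genes, np.inf)
        up_in_all = np.ones(n_genes, dtype=bool)
        n_comp = 0
        for other in clusters.tolist():
            if other == cl:
                continue
            a, b = min(cl, other), max(cl, other)
            sub = records[(records.cluster_a == a) & (records.cluster_b == b)]
            q = sub["q"].to_numpy()
            lfc = sub["log2fc"].to_numpy()
            if cl == b:
                lfc = -lfc
            up = group_mean[cl] > group_mean[other]
            up_in_all &= up
            max_q = np.maximum(max_q, q)
            min_lfc = np.minimum(min_lfc, lfc)
            n_comp += 1
        max_q = np.where(up_in_all, max_q, 1.0)
        summary_rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cluster": cl,
                    "max_q": max_q,
                    "min_log2fc": min_lfc,
                    "n_comparisons": n_comp,
                }
            )
        )
    summary = pd.concat(summary_rows, ignore_index=True)
    logger.info(
        "pairwise_de: %d genes x %d cluster pairs",
        n_genes, len(list(combinations(clusters, 2))),
    )
    return DETable(records=records, summary=summary, clusters=tuple(clusters.tolist()))


def de_by_max_fdr(
    t: DETable, threshold: float = 1e-10, min_log2fc: float = 0.0
) -> dict[int, frozenset[str]]:
    """Cluster → genes with max_q < threshold and min pairwise
    log2FC > min_log2fc; monotone in the threshold."""
    out: dict[int, frozenset[str]] = {}
    for cl in t.clusters:
        sub = t.summary[t.summary.cluster == cl]
        hits = sub[(sub.max_q < threshold) & (sub.min_log2fc > min_log2fc)]
        out[cl] = frozenset(hits["gene"])
    return out


@dataclass
class SignatureEntry:
    """Ordered signature genes of one cluster: rank product, permutation
    p and BH-adjusted p, sorted by (adjusted p, RP)."""

    cluster: int
    table: pd.DataFrame


def rank_product_signatures(
    t: DETable,
    cluster: int,
    n_perm: int = 10000,
    seed: int = 0,
    fdr_threshold: float = 1e-10,
) -> SignatureEntry:
    """Rank-product signature genes for one cluster.

    Candidates pass FDR < ``fdr_threshold`` in all of the cluster's
    comparisons (in the up direction).  Within each comparison the
    candidates are ranked by FDR (1 = smallest, midranks on ties); the
    rank product is the geometric mean of a gene's ranks, and its
    p-value comes from ``n_perm`` independent within-comparison rank
    shuffles: p = (1 + #{permuted RP <= observed}) / (n_perm + 1), BH
    adjusted across candidates.
    """
    if cluster not in t.clusters:
        raise ValidationError(f"unknown cluster {cluster}")
    sub = t.summary[t.summary.cluster == cluster]
    candidates = sub[sub.max_q < fdr_threshold]["gene"].tolist()
    if not candidates:
        logger.warning("rank_product_signatures: cluster %s has no candidates", cluster)
        return SignatureEntry(
            cluster, pd.DataFrame(columns=["gene", "rank_product", "p", "q"])
        )

    from scipy.stats import rankdata

    rank_rows = []
    for other in t.clusters:
        if other == cluster:
            continue
        a, b = min(cluster, other), max(cluster, other)
        rec = t.records[(t.records.cluster_a == a) & (t.records.cluster_b == b)]
        qmap = dict(zip(rec["gene"], rec["q"]))
        qs = np.array([qmap[g] for g in candidates])
        rank_rows.append(rankdata(qs))
    ranks = np.vstack(rank_rows)  # comparisons × candidates
    m, g = ranks.shape
    obs_rp = np.exp(np.log(ranks).mean(axis=0))

    rng = np.random.default_rng(seed)
    count = np.zeros(g)
    log_ranks = np.log(ranks)
    for _ in range(n_perm):
        perm = np.empty_like(log_ranks)
        for i in range(m):
            perm[i] = log_ranks[i, rng.permutation(g)]
        perm_rp = np.exp(perm.mean(axis=0))
        count += perm_rp <= obs_rp + 1e-12
    p = (1.0 + count) / (n_perm + 1.0)
    q = bh_adjust(p)
    table = (
        pd.DataFrame({"gene": candidates, "rank_product": obs_rp, "p": p, "q": q})
        .sort_values(["q", "rank_product", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return SignatureEntry(cluster, table)


def module_score(lm: LogMatrix, gs: GeneSet) -> np.ndarray:
    """Per-cell mean expression of the set minus the per-cell mean over
    all detected genes; absent set genes are dropped with a warning."""
    idx = [i for i, g in enumerate(lm.gene_ids) if g in gs.genes]
    if not idx:
        raise ValidationError(f"no gene of set {gs.name!r} present in matrix")
    if len(idx) < len(gs.genes):
        logger.warning(
            "module_score: %d/%d genes of %r absent from matrix",
            len(gs.genes) - len(idx), len(gs.genes), gs.name,
        )
    dense = lm.dense()
    set_mean = dense[idx].mean(axis=0)
    all_mean = dense.mean(axis=0)
    return set_mean - all_mean


@dataclass
class ModuleScoreTable:
    scores: pd.DataFrame  # cells × gene sets
    assigned: pd.Series  # per-cell type label ("unassigned" on exact ties)
    z_validation: pd.DataFrame | None = None


def score_gene_sets(lm: LogMatrix, gene_sets: list[GeneSet]) -> pd.DataFrame:
    if len(gene_sets) < 2:
        raise ValidationError("need at least 2 gene sets")
    return pd.DataFrame(
        {gs.name: module_score(lm, gs) for gs in gene_sets}, index=lm.cell_ids
    )


def assign_cell_types(
    scores: pd.DataFrame,
    lm: LogMatrix | None = None,
    gene_sets: list[GeneSet] | None = None,
) -> ModuleScoreTable:
    """Assign each cell to the argmax module score (exact ties →
    "unassigned").

    When ``lm`` and ``gene_sets`` are given, a validation table is
    added: per assigned type, the mean z-scored expression (per gene,
    across cells) of each type's gene set — expected maximal on the
    diagonal.
    """
    if scores.shape[1] < 2:
        raise ValidationError("need scores for at least 2 gene sets")
    vals = scores.to_numpy()
    best = vals.argmax(axis=1)
    top = vals[np.arange(len(vals)), best]
    tie = (vals == top[:, None]).sum(axis=1) > 1
    assigned = pd.Series(
        np.where(tie, "unassigned", scores.columns.to_numpy()[best]),
        index=scores.index,
        name="assigned_type",
    )

    z_val = None
    if lm is not None and gene_sets is not None:
        dense = lm.dense()
        mu = dense.mean(axis=1, keepdims=True)
        sd = dense.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (dense - mu) / np.maximum(sd, 1e-12), 0.0)
        set_idx = {
            gs.name: [i for i, g in enumerate(lm.gene_ids) if g in gs.genes]
            for gs in gene_sets
        }
        rows = {}
        for t in scores.columns:
            members = np.where(assigned.to_numpy() == t)[0]
            if members.size == 0:
                continue
            rows[t] = {
                name: float(z[np.ix_(idx, members)].mean()) if idx else np.nan
                for name, idx in set_idx.items()
            }
        z_val = pd.DataFrame(rows).T
        z_val.index.name = "assigned_type"
    return ModuleScoreTable(scores=scores, assigned=assigned, z_validation=z_val)
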
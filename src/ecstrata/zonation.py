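"""Crypt–villus annotation, randomization-KS testing, co-expression.

Clusters are annotated along the crypt–villus axis from the relative
expression of a crypt marker (Tac1), a villus marker (Sct) and a
progenitor marker (Neurog3).  Whether a target gene's expression depends
on a grouping (cluster or region) is tested against a randomization
null: the observed statistic is the largest two-sample KS D between the
gene's expression inside any one group and the remaining cells, and the
null distribution is the same statistic for control genes drawn (with
replacement) from a pool matched on overall mean log expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import MatchingError, ValidationError
from .io_core import LogMatrix, logger
from .stats_core import hypergeom_test


@dataclass
class AxisAnnotation:
    """Cluster → crypt/villus/progenitor label with supporting means."""

    labels: dict[int, str]
    stats: pd.DataFrame


def annotate_crypt_villus(
    lm: LogMatrix,
    labels: np.ndarray,
    crypt_gene: str = "Tac1",
    villus_gene: str = "Sct",
    progenitor_gene: str = "Neurog3",
) -> AxisAnnotation:
    """Annotate clusters as progenitor, crypt or villus.

    A cluster is a progenitor when its mean progenitor-gene expression
    is maximal among clusters and exceeds the across-cluster mean by at
    least one SD of the cluster means; otherwise it is crypt when its
    mean crypt-gene expression beats the villus gene, else villus.
    """
    labels = np.asarray(labels)
    dense = lm.dense()
    rows = {}
    for gene in (crypt_gene, villus_gene, progenitor_gene):
        rows[gene] = dense[lm.gene_index(gene)]
    clusters = np.unique(labels)
    stats = pd.DataFrame(
        {
            "cluster": clusters,
            "mean_crypt": [rows[crypt_gene][labels == c].mean() for c in clusters],
            "mean_villus": [rows[villus_gene][labels == c].mean() for c in clusters],
            "mean_progenitor": [
                rows[progenitor_gene][labels == c].mean() for c in clusters
            ],
        }
    )
    prog = stats["mean_progenitor"].to_numpy()
    prog_cut = prog.mean() + prog.std()
    out: dict[int, str] = {}
    for i, c in enumerate(clusters.tolist()):
        if prog[i] == prog.max() and prog[i] > prog_cut and clusters.size > 1:
            out[c] = "progenitor"
        elif stats.loc[i, "mean_crypt"] > stats.loc[i, "mean_villus"]:
            out[c] = "crypt"
        else:
            out[c] = "villus"
    return AxisAnnotation(labels=out, stats=stats)


@dataclass
class RandomizationResult:
    observed_d: float
    null_ds: np.ndarray
    median_null_d: float
    p_value: float
    n_rand: int
    seed: int
    n_matched: int
    group_medians: pd.Series

    def __post_init__(self) -> None:
        if not (1.0 / (self.n_rand + 1) <= self.p_value <= 1.0):
            raise ValidationError("empirical p outside its admissible range")
        if len(self.null_ds) != self.n_rand:
            raise ValidationError("null Ds must have length n_rand")


def _group_max_ks_d(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """For each row (gene), the max over groups of the two-sample KS D
    between within-group and out-of-group values.  Vectorized over rows;
    tied values are handled by evaluating the ECDF gap only at the last
    value of each tie run."""
    n_rows, n = x.shape
    order = np.argsort(x, axis=1, kind="stable")
    xs = np.take_along_axis(x, order, axis=1)
    last_of_run = np.ones((n_rows, n), dtype=bool)
    last_of_run[:, :-1] = xs[:, 1:] != xs[:, :-1]
    best = np.zeros(n_rows)
    for g in np.unique(groups):
        mask = groups == g
        n_in = int(mask.sum())
        n_out = n - n_in
        if n_in == 0 or n_out == 0:
            continue
        sorted_mask = mask[order]
        cum_in = np.cumsum(sorted_mask, axis=1) / n_in
        cum_out = np.cumsum(~sorted_mask, axis=1) / n_out
        d = np.abs(cum_in - cum_out)
        d[~last_of_run] = 0.0
        best = np.maximum(best, d.max(axis=1))
    return best


def randomization_ks(
    lm: LogMatrix,
    target_gene: str,
    grouping: np.ndarray,
    n_rand: int = 500,
    matching: str = "mean_expression",
    matching_band: float = 0.25,
    seed: int = 0,
) -> RandomizationResult:
    """Randomization KS test of group-dependent expression.

    The observed statistic is the largest KS D between the target gene's
    per-cell expression inside any one group versus the remaining cells.
    Controls are genes sampled with replacement from the pool whose
    overall mean log expression lies within ``matching_band`` of the
    target's (the target itself is excluded, so a strongly
    group-specific gene can reach the 1/(n_rand+1) floor), each scored
    by the same statistic; the empirical p uses the add-one rule, so it
    is never 0.
    """
    grouping = np.asarray(grouping)
    if np.unique(grouping).size < 2:
        raise ValidationError("need at least 2 groups")
    dense = lm.dense()
    ti = lm.gene_index(target_gene)
    gene_means = dense.mean(axis=1)

    if matching == "mean_expression":
        eligible = np.where(np.abs(gene_means - gene_means[ti]) <= matching_band)[0]
    elif matching == "none":
        eligible = np.arange(dense.shape[0])
    else:
        raise ValidationError(f"unknown matching mode {matching!r}")
    eligible = eligible[eligible != ti]
    if eligible.size < 10:
        raise MatchingError(
            f"only {eligible.size} genes matched within ±{matching_band}; "
            "widen the matching band"
        )

    pool_d = _group_max_ks_d(dense[eligible], grouping)
    observed = float(_group_max_ks_d(dense[ti : ti + 1], grouping)[0])
    rng = np.random.default_rng(seed)
    null_ds = pool_d[rng.integers(0, eligible.size, size=n_rand)]
    p = (1.0 + int(np.sum(null_ds >= observed - 1e-12))) / (n_rand + 1.0)

    target = dense[ti]
    medians = pd.Series(
        {g: float(np.median(target[grouping == g])) for g in np.unique(grouping)},
        name=target_gene,
    )
    logger.debug(
        "randomization_ks: %s observed D=%.3f, p=%.4g (%d matched genes)",
        target_gene, observed, p, eligible.size,
    )
    return RandomizationResult(
        observed_d=observed,
        null_ds=null_ds,
        median_null_d=float(np.median(null_ds)),
        p_value=p,
        n_rand=n_rand,
        seed=seed,
        n_matched=int(eligible.size),
        group_medians=medians,
    )


@dataclass
class CoexpressionTable:
    combination_counts: pd.DataFrame  # one row per exact marker combination
    marginal_counts: pd.Series
    enrichment: pd.DataFrame
    universe_size: int


def positivity_calls(lm: LogMatrix, markers: list[str], min_expr: float = 0.0) -> pd.DataFrame:
    """Per-cell positivity: expression strictly above ``min_expr``
    (default: any detected UMI)."""
    dense = lm.dense()
    return pd.DataFrame(
        {g: dense[lm.gene_index(g)] > min_expr for g in markers}, index=lm.cell_ids
    )


def coexpression_enrichment(
    calls: pd.DataFrame, universe: str = "any_positive"
) -> CoexpressionTable:
    """Marker combination counts and hypergeometric enrichment.

    The universe is either every cell positive for at least one marker
    (default, mirroring marker-positive survey populations) or all
    cells.  For each marker pair (A, B) and each third marker X, the
    enrichment of X inside the A+B+ population is
    hypergeom(k = #A+B+X+, K = #X+, n = #A+B+, N = universe).
    """
    if calls.shape[1] < 2:
        raise ValidationError("need at least 2 markers")
    markers = list(calls.columns)
    vals = calls.to_numpy(dtype=bool)
    if universe == "any_positive":
        in_universe = vals.any(axis=1)
    elif universe == "all_cells":
        in_universe = np.ones(len(calls), dtype=bool)
    else:
        raise ValidationError(f"unknown universe {universe!r}")
    if not in_universe.any():
        raise ValidationError("empty universe: no positive cells")
    u = vals[in_universe]
    n_u = int(in_universe.sum())

    combo_rows = []
    for r in range(1, len(markers) + 1):
        for combo in combinations(range(len(markers)), r):
            exact = np.ones(n_u, dtype=bool)
            for j in range(len(markers)):
                exact &= u[:, j] if j in combo else ~u[:, j]
            combo_rows.append(
                {
                    "combination": "+".join(markers[j] for j in combo),
                    "n_markers": r,
                    "count": int(exact.sum()),
                }
            )
    combo_df = pd.DataFrame(combo_rows)
    marginals = pd.Series(
        {m: int(u[:, j].sum()) for j, m in enumerate(markers)}, name="positive_cells"
    )

    enr_rows = []
    if len(markers) >= 3:
        for a, b in combinations(range(len(markers)), 2):
            ab = u[:, a] & u[:, b]
            n_ab = int(ab.sum())
            for xj in range(len(markers)):
                if xj in (a, b):
                    continue
                k = int((ab & u[:, xj]).sum())
                big_k = int(u[:, xj].sum())
                res = hypergeom_test(k, big_k, n_ab, n_u) if n_ab else None
                enr_rows.append(
                    {
                        "pair": f"{markers[a]}+{markers[b]}",
                        "third_marker": markers[xj],
                        "k": k,
                        "K": big_k,
                        "n": n_ab,
                        "N": n_u,
                        "p": res.p_value if res else np.nan,
                    }
                )
    enr_df = pd.DataFrame(enr_rows)
    return CoexpressionTable(
        combination_counts=combo_df,
        marginal_counts=marginals,
        enrichment=enr_df,
        universe_size=n_u,
    )
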
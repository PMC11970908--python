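"""Gene/cell quality filters and heuristic doublet flagging.

Filters follow the strict-boundary reading of the stated thresholds:
genes kept when expressed in >= min_cells cells ("fewer than 10" removes
only <10), cells kept when they detect >= min_genes genes and their
mitochondrial UMI fraction is <= max_mito_frac (strict ">" removes).
Filter order is genes first, then cells (detected-gene counts are taken
on the filtered gene set).  Both filters are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture

from .errors import EmptyOutputError, ValidationError
from .io_core import CountMatrix, GeneSet, LogMatrix, logger

#: A class signature counts as "present" in a cell when its module score
#: lies at least this far along the way from the non-class background
#: mean to the assigned-class mean.  A doublet's minority parent
#: signature is diluted roughly two-fold on the count scale, which the
#: log transform compresses to well above a third of the pure-class
#: level, so one third (plus margin) separates doublets from background.
SIGNATURE_PRESENCE_FRACTION = 0.35


@dataclass
class QcReport:
    genes_removed: int = 0
    cells_removed_low_genes: int = 0
    cells_removed_mito: int = 0
    doublets_removed: int = 0
    thresholds: dict = field(default_factory=dict)


def filter_genes(m: CountMatrix, min_cells: int = 10) -> tuple[CountMatrix, QcReport]:
    """Drop genes with nonzero counts in fewer than ``min_cells`` cells."""
    cells_per_gene = (m.values > 0).sum(axis=1).A1
    keep = cells_per_gene >= min_cells
    if not keep.any():
        raise EmptyOutputError("gene filter removed every gene")
    out = CountMatrix(
        m.values[keep],
        [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.cell_ids),
        m.mito_flags[keep],
    )
    report = QcReport(
        genes_removed=int((~keep).sum()), thresholds={"min_cells": min_cells}
    )
    logger.info("filter_genes: %d -> %d genes", m.n_genes, out.n_genes)
    return out, report


def filter_cells(
    m: CountMatrix, min_genes: int = 500, max_mito_frac: float = 0.10
) -> tuple[CountMatrix, QcReport]:
    """Drop low-complexity and high-mitochondrial cells.

    A cell is removed when it detects fewer than ``min_genes`` genes, or
    when more than ``max_mito_frac`` of its UMIs come from mitochondrial
    genes (a cell at exactly the boundary is retained in both cases).
    """
    detected = (m.values > 0).sum(axis=0).A1
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    mito_umis = np.asarray(m.values[m.mito_flags].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_umis / np.maximum(totals, 1), 0.0)
    low_genes = detected < min_genes
    high_mito = mito_frac > max_mito_frac
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise EmptyOutputError("cell filter removed every cell")
    out = CountMatrix(
        m.values[:, keep],
        list(m.gene_ids),
        [c for c, k in zip(m.cell_ids, keep) if k],
        m.mito_flags,
    )
    report = QcReport(
        cells_removed_low_genes=int(low_genes.sum()),
        cells_removed_mito=int((high_mito & ~low_genes).sum()),
        thresholds={"min_genes": min_genes, "max_mito_frac": max_mito_frac},
    )
    logger.info("filter_cells: %d -> %d cells", m.n_cells, out.n_cells)
    return out, report


def apply_qc(
    m: CountMatrix,
    min_cells: int = 10,
    min_genes: int = 500,
    max_mito_frac: float = 0.10,
    exclude_genes: GeneSet | None = None,
) -> tuple[CountMatrix, QcReport]:
    """Standard QC: optional exclusion list (e.g. non-coding genes), then
    gene filter, then cell filter."""
    if exclude_genes is not None:
        keep = np.array([g not in exclude_genes.genes for g in m.gene_ids])
        m = CountMatrix(
            m.values[keep],
            [g for g, k in zip(m.gene_ids, keep) if k],
            list(m.cell_ids),
            m.mito_flags[keep],
        )
    m2, rg = filter_genes(m, min_cells)
    m3, rc = filter_cells(m2, min_genes, max_mito_frac)
    report = QcReport(
        genes_removed=rg.genes_removed,
        cells_removed_low_genes=rc.cells_removed_low_genes,
        cells_removed_mito=rc.cells_removed_mito,
        thresholds={**rg.thresholds, **rc.thresholds},
    )
    return m3, report


def _library_log_matrix(m: CountMatrix) -> LogMatrix:
    """Quick library-size-normalized log2 matrix for doublet scoring."""
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    med = np.median(totals[totals > 0])
    factors = np.where(totals > 0, totals / med, 1.0)
    vals = m.values.tocsc(copy=True).astype(float)
    vals.data /= np.repeat(factors, np.diff(vals.indptr))
    vals.data = np.log2(vals.data + 1.0)
    return LogMatrix(vals.tocsr(), list(m.gene_ids), list(m.cell_ids), factors)


def flag_doublets(
    m: CountMatrix,
    class_signatures: list[GeneSet],
    umi_bimodality_min_sep: float = 0.5,
    z_threshold: float = 2.0,
    random_state: int = 0,
) -> np.ndarray:
    """Flag probable doublets; cells are not removed.

    Criterion 1 (mixed signatures): each cell is scored against every
    class signature (module score on library-normalized log expression)
    and assigned to the top-scoring class.  A signature counts as
    "present" when the cell's score exceeds the non-class background by
    ``z_threshold`` SDs and lies above a fixed fraction
    (:data:`SIGNATURE_PRESENCE_FRACTION`) of the way from the
    background mean to the assigned-class mean; a cell with >= 2
    present signatures is flagged.

    Criterion 2 (UMI bimodality): within each assigned class, a
    two-component Gaussian mixture is fit to log2 total UMIs; when a
    secondary (minor-weight) high mode sits >= ``umi_bimodality_min_sep``
    log2 units above the main one, its members are flagged.
    """
    from .markers import module_score

    if len(class_signatures) < 2:
        raise ValidationError("need at least 2 class signatures")
    gene_set = set(m.gene_ids)
    missing = {
        gs.name: sorted(gs.genes - gene_set)
        for gs in class_signatures
        if gs.genes - gene_set
    }
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")

    lm = _library_log_matrix(m)
    n = m.n_cells
    scores = np.column_stack([module_score(lm, gs) for gs in class_signatures])
    assigned = scores.argmax(axis=1)

    present = np.zeros_like(scores, dtype=bool)
    for s in range(len(class_signatures)):
        in_class = assigned == s
        bg = ~in_class
        if bg.sum() < 2 or in_class.sum() < 1:
            continue
        mu_bg, sd_bg = scores[bg, s].mean(), scores[bg, s].std()
        mu_in = scores[in_class, s].mean()
        cut = max(
            mu_bg + z_threshold * sd_bg,
            mu_bg + SIGNATURE_PRESENCE_FRACTION * (mu_in - mu_bg),
        )
        present[:, s] = scores[:, s] >= cut
    flagged = present.sum(axis=1) >= 2

    log_umis = np.log2(np.asarray(m.values.sum(axis=0)).ravel().astype(float) + 1.0)
    for s in range(len(class_signatures)):
        idx = np.where(assigned == s)[0]
        if idx.size < 10:
            continue
        gm = GaussianMixture(2, random_state=random_state, n_init=3)
        vals = log_umis[idx].reshape(-1, 1)
        gm.fit(vals)
        means = gm.means_.ravel()
        hi = int(means.argmax())
        if means[hi] - means[1 - hi] < umi_bimodality_min_sep:
            continue
        if gm.weights_[hi] >= 0.5:  # the high mode is the main population
            continue
        post = gm.predict_proba(vals)[:, hi]
        flagged[idx[post > 0.5]] = True

    logger.info("flag_doublets: %d/%d cells flagged", int(flagged.sum()), n)
    return flagged
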
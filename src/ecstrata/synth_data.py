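"""Synthetic inputs with known ground truth for every pipeline stage.

The count simulator emulates droplet scRNA-seq UMI data: negative-binomial
counts with per-gene baselines, planted clusters demarcated by marker
fold-changes (mirroring the regional structure of gut EC cells), a
mitochondrial gene block, a crypt→villus expression gradient, log-uniform
library size factors and inter-cluster doublets.  Companion generators
produce FISH spot images with controlled cross-channel co-positivity,
gut-transit fluorescence profiles and qPCR Ct tables.  All generators are
pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage.draw import disk as draw_disk

from .errors import ConfigError, GenerationError, ValidationError
from .fish_quant import ChannelMask, RoiMask
from .io_core import REGIONS, CountMatrix, logger
from .physiology import N_SI_SEGMENTS, TransitProfile

#: Protein-coding genes of the mouse mitochondrial genome.
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for the count simulator.

    Defaults describe a mid-sized gut EC-cell experiment: a few thousand
    cells in region-demarcated clusters, ~2000 informative genes, strong
    cluster markers (log2FC 3, i.e. 8-fold), a ~5% mitochondrial UMI
    fraction, a small doublet rate and a 2-fold library-depth spread.
    """

    n_clusters: int = 6
    cells_per_cluster: int = 300
    n_genes: int = 2000
    n_marker_genes_per_cluster: int = 20
    marker_log2fc: float = 3.0
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    mito_fraction: float = 0.05
    doublet_rate: float = 0.05
    gradient_genes: int = 50
    size_factor_spread: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.cells_per_cluster, self.n_genes) < 1:
            raise ConfigError("counts must be positive")
        if not (0 <= self.mito_fraction <= 1) or not (0 <= self.doublet_rate <= 1):
            raise ConfigError("rates must lie in [0, 1]")
        if self.marker_log2fc < 0:
            raise ConfigError("marker_log2fc must be >= 0")
        if self.size_factor_spread < 1:
            raise ConfigError("size_factor_spread must be >= 1")
        reserved = (
            self.n_marker_genes_per_cluster * self.n_clusters
            + len(MITO_GENES)
            + self.gradient_genes
        )
        if reserved > self.n_genes:
            raise ConfigError(
                f"marker/mito/gradient genes ({reserved}) exceed n_genes "
                f"({self.n_genes})"
            )


@dataclass
class SynthTruth:
    true_cluster: np.ndarray
    true_doublet: np.ndarray
    true_size_factor: np.ndarray
    true_markers: dict[int, frozenset[str]]
    true_gradient_position: np.ndarray


def benchmark_config(seed: int = 1) -> SynthConfig:
    """The standard planted-cluster benchmark: 6 clusters × 300 cells,
    2000 genes, 20 markers per cluster at log2FC 3, no doublets or
    gradient so the planted clusters are the only structure."""
    return SynthConfig(
        n_clusters=6,
        cells_per_cluster=300,
        n_genes=2000,
        n_marker_genes_per_cluster=20,
        marker_log2fc=3.0,
        doublet_rate=0.0,
        gradient_genes=0,
        seed=seed,
    )


def _gene_names(cfg: SynthConfig) -> tuple[list[str], np.ndarray, dict[int, list[int]], list[int], list[int]]:
    """Lay out the gene panel: mito block, per-cluster markers, gradient
    genes (half increasing toward the villus — the first named Sct — and
    half decreasing — the first named Tac1), then background genes."""
    names: list[str] = []
    mito_idx = list(range(len(MITO_GENES)))
    names.extend(MITO_GENES)
    markers: dict[int, list[int]] = {}
    for k in range(cfg.n_clusters):
        idx = []
        for j in range(cfg.n_marker_genes_per_cluster):
            idx.append(len(names))
            names.append(f"Mk{k}_{j}")
        markers[k] = idx
    grad_idx: list[int] = []
    n_up = cfg.gradient_genes // 2 + cfg.gradient_genes % 2
    for j in range(cfg.gradient_genes):
        grad_idx.append(len(names))
        if j == 0 and cfg.gradient_genes >= 2:
            names.append("Sct")
        elif j == n_up and cfg.gradient_genes >= 2:
            names.append("Tac1")
        else:
            names.append(f"Grad{'Up' if j < n_up else 'Dn'}{j}")
    while len(names) < cfg.n_genes:
        names.append(f"Gene{len(names)}")
    mito_flags = np.zeros(cfg.n_genes, dtype=bool)
    mito_flags[mito_idx] = True
    return names, mito_flags, markers, grad_idx[:n_up], grad_idx[n_up:]


def simulate_counts(cfg: SynthConfig) -> tuple[CountMatrix, pd.DataFrame, SynthTruth]:
    """Simulate a planted-cluster UMI count matrix.

    Counts are NB(mean, dispersion) via the gamma–Poisson mixture; the
    markers of cluster k have mean × 2^marker_log2fc inside k; per-cell
    means are scaled by log-uniform size factors (max/min spread =
    ``size_factor_spread``); the mitochondrial block contributes
    ≈ ``mito_fraction`` of UMIs in singlets; gradient-gene means are
    linear in the cell's crypt→villus position; doublets are appended as
    sums of two fresh cells from different clusters.
    """
    rng = np.random.default_rng(cfg.seed)
    names, mito_flags, markers, grad_up, grad_dn = _gene_names(cfg)

    base = cfg.nb_mean * np.exp(rng.normal(0.0, 0.5, size=cfg.n_genes))
    # scale the mito block to the requested UMI share
    non_mito_total = base[~mito_flags].sum()
    if cfg.mito_fraction > 0:
        mito_total = cfg.mito_fraction / (1 - cfg.mito_fraction) * non_mito_total
        base[mito_flags] = mito_total / mito_flags.sum()
    else:
        base[mito_flags] = 0.0

    n_singlets = cfg.n_clusters * cfg.cells_per_cluster
    clusters = np.repeat(np.arange(cfg.n_clusters), cfg.cells_per_cluster)
    positions = rng.uniform(0.0, 1.0, size=n_singlets)
    half_log = 0.5 * np.log(cfg.size_factor_spread)
    factors = np.exp(rng.uniform(-half_log, half_log, size=n_singlets))

    def _mean_matrix(cl: np.ndarray, pos: np.ndarray, fac: np.ndarray) -> np.ndarray:
        mu = np.tile(base[:, None], (1, cl.size))
        fc = 2.0**cfg.marker_log2fc
        for k, idx in markers.items():
            mu[np.ix_(idx, np.where(cl == k)[0])] *= fc
        if grad_up:
            mu[grad_up, :] *= 0.5 + pos[None, :]
        if grad_dn:
            mu[grad_dn, :] *= 1.5 - pos[None, :]
        return mu * fac[None, :]

    def _sample_nb(mu: np.ndarray) -> np.ndarray:
        lam = np.where(
            mu > 0, rng.gamma(cfg.nb_dispersion, np.maximum(mu, 1e-300) / cfg.nb_dispersion), 0.0
        )
        return rng.poisson(lam)

    counts = _sample_nb(_mean_matrix(clusters, positions, factors))

    n_doublets = int(round(cfg.doublet_rate * n_singlets))
    if n_doublets:
        ca = rng.integers(0, cfg.n_clusters, size=n_doublets)
        cb = (ca + 1 + rng.integers(0, cfg.n_clusters - 1, size=n_doublets)) % cfg.n_clusters
        pos_d = rng.uniform(0.0, 1.0, size=2 * n_doublets)
        fac_d = np.exp(rng.uniform(-half_log, half_log, size=2 * n_doublets))
        parents = np.concatenate([ca, cb])
        d_counts = _sample_nb(_mean_matrix(parents, pos_d, fac_d))
        d_sum = d_counts[:, :n_doublets] + d_counts[:, n_doublets:]
        counts = np.concatenate([counts, d_sum], axis=1)
        clusters = np.concatenate([clusters, ca])
        positions = np.concatenate([positions, pos_d[:n_doublets]])
        factors = np.concatenate([factors, fac_d[:n_doublets] + fac_d[n_doublets:]])
    doublet_flags = np.zeros(n_singlets + n_doublets, dtype=bool)
    doublet_flags[n_singlets:] = True

    n_cells = counts.shape[1]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(sp.csr_matrix(counts), names, cell_ids, mito_flags)

    region_of_cluster = [REGIONS[k % 4] for k in range(cfg.n_clusters)]
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "region": [region_of_cluster[k] for k in clusters],
            "reporter": "positive",
        }
    )
    truth = SynthTruth(
        true_cluster=clusters,
        true_doublet=doublet_flags,
        true_size_factor=factors,
        true_markers={k: frozenset(names[i] for i in idx) for k, idx in markers.items()},
        true_gradient_position=positions,
    )
    logger.info(
        "simulate_counts: %d genes x %d cells (%d doublets), seed=%d",
        cfg.n_genes, n_cells, n_doublets, cfg.seed,
    )
    return cm, meta, truth


@dataclass
class FishTruth:
    cells: pd.DataFrame  # cell, row, col, roi, one bool column per channel


def simulate_fish_image(
    width: int,
    height: int,
    n_cells: int,
    channel_probs: tuple[float, ...],
    coloc_prob: float,
    spots_per_positive_cell: int = 3,
    spot_radius: int = 2,
    seed: int = 0,
    channel_names: tuple[str, ...] | None = None,
    cell_radius: int = 6,
) -> tuple[list[ChannelMask], RoiMask, FishTruth]:
    """Simulate non-overlapping cells emitting spot disks per channel.

    The first two channels follow the exact 2×2 joint distribution with
    marginals ``channel_probs[:2]`` and P(both) = ``coloc_prob`` (must be
    within the Fréchet bounds); additional channels are independent.
    Each positive (cell, channel) receives one spot at the cell center
    (guaranteeing detectable cross-channel overlap for co-positive
    cells) plus jittered satellite spots.  A ROI mask marks the top half
    of the frame as crypt (1) and the bottom half as villus (2).
    """
    if len(channel_probs) < 2:
        raise ValidationError("need at least 2 channels")
    if not all(0 <= p <= 1 for p in channel_probs) or not (0 <= coloc_prob <= 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    p1, p2 = channel_probs[0], channel_probs[1]
    if coloc_prob > min(p1, p2) + 1e-12 or coloc_prob < max(0.0, p1 + p2 - 1) - 1e-12:
        raise ValidationError(
            f"coloc_prob {coloc_prob} incompatible with marginals {p1}, {p2}"
        )
    channel_names = channel_names or tuple(
        f"ch{i + 1}" for i in range(len(channel_probs))
    )
    rng = np.random.default_rng(seed)

    margin = cell_radius + spot_radius + 3
    min_sep = 4 * cell_radius
    if 2 * margin >= min(width, height):
        raise ValidationError("frame too small for the requested geometry")
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 500 * max(n_cells, 1):
            raise GenerationError(
                f"could not pack {n_cells} cells into {width}x{height}"
            )
        r = int(rng.integers(margin, height - margin))
        c = int(rng.integers(margin, width - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))

    u = rng.random(n_cells)
    both = u < coloc_prob
    a_only = (~both) & (u < coloc_prob + (p1 - coloc_prob))
    b_only = (~both) & (~a_only) & (u < p1 + (p2 - coloc_prob))
    positivity = np.zeros((n_cells, len(channel_probs)), dtype=bool)
    positivity[:, 0] = both | a_only
    positivity[:, 1] = both | b_only
    for j in range(2, len(channel_probs)):
        positivity[:, j] = rng.random(n_cells) < channel_probs[j]

    masks = [np.zeros((height, width), dtype=bool) for _ in channel_probs]
    jitter_max = max(cell_radius - spot_radius - 1, 0)
    for i, (r0, c0) in enumerate(centers):
        for j in range(len(channel_probs)):
            if not positivity[i, j]:
                continue
            spots = [(r0, c0)]
            for _ in range(spots_per_positive_cell - 1):
                dr = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
                dc = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
                spots.append((r0 + dr, c0 + dc))
            for sr, scol in spots:
                rr, cc = draw_disk((sr, scol), spot_radius + 0.5, shape=(height, width))
                masks[j][rr, cc] = True

    roi = np.ones((height, width), dtype=int)
    roi[height // 2 :, :] = 2
    truth_df = pd.DataFrame(
        {
            "cell": np.arange(n_cells),
            "row": [r for r, _ in centers],
            "col": [c for _, c in centers],
            "roi": [1 if r < height // 2 else 2 for r, _ in centers],
        }
    )
    for j, name in enumerate(channel_names):
        truth_df[name] = positivity[:, j]
    channel_masks = [ChannelMask(m, n) for m, n in zip(masks, channel_names)]
    return channel_masks, RoiMask(roi), FishTruth(truth_df)


def simulate_transit(
    mode: str,
    total: float = 100.0,
    segment: int | None = None,
    custom=None,
    stomach: float = 0.0,
    colon: float = 0.0,
) -> TransitProfile:
    """Build a transit fluorescence profile.

    ``mode`` is one of ``all_in_segment`` (all SI signal in one segment),
    ``uniform`` (T/10 per segment) or ``custom`` (vector passed through).
    """
    if mode == "all_in_segment":
        if segment is None or not (1 <= segment <= N_SI_SEGMENTS):
            raise ValidationError("segment must be in 1..10")
        si = np.zeros(N_SI_SEGMENTS)
        si[segment - 1] = total
    elif mode == "uniform":
        si = np.full(N_SI_SEGMENTS, total / N_SI_SEGMENTS)
    elif mode == "custom":
        si = np.asarray(custom, dtype=float)
        if np.any(si < 0):
            raise ValidationError("fluorescence must be non-negative")
    else:
        raise ValidationError(f"unknown transit mode {mode!r}")
    return TransitProfile(stomach=stomach, si_segments=si, colon=colon)


#: Baseline Ct cycles per housekeeping gene, constant across groups.
_HK_BASELINE = {"B2m": 20.0, "Gapdh": 18.0, "Rpl13a": 22.0}


def simulate_qpcr(
    n_targets: int,
    groups: list[str],
    true_log2fc: np.ndarray | None = None,
    hk_genes: tuple[str, str, str] = ("B2m", "Gapdh", "Rpl13a"),
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    baseline_ct: float = 25.0,
) -> pd.DataFrame:
    """Simulate a Ct table: Ct = baseline − log2(relative expression) + noise.

    ``true_log2fc`` has shape (n_targets, n_groups) relative to the first
    group; housekeeping genes are fold-change 1 everywhere.
    """
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    lfc = (
        np.zeros((n_targets, len(groups)))
        if true_log2fc is None
        else np.asarray(true_log2fc, dtype=float)
    )
    if lfc.shape != (n_targets, len(groups)):
        raise ConfigError("true_log2fc must be (n_targets, n_groups)")
    rng = np.random.default_rng(seed)
    records = []
    hk_base = [_HK_BASELINE.get(g, 20.0) for g in hk_genes]
    for gi, group in enumerate(groups):
        for rep in range(n_replicates):
            sample = f"{group}_s{rep + 1}"
            for ti in range(n_targets):
                ct = baseline_ct - lfc[ti, gi] + rng.normal(0.0, ct_noise_sd)
                records.append(("T%d" % (ti + 1), sample, group, ct))
            for hk, base_ct in zip(hk_genes, hk_base):
                ct = base_ct + rng.normal(0.0, ct_noise_sd)
                records.append((hk, sample, group, ct))
    return pd.DataFrame(records, columns=["gene", "sample", "group", "ct"])
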
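"""Shared fixtures: the standard planted-cluster benchmark pipeline."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from ecstrata import normalize, qc, synth_data
from ecstrata.cluster import cluster_cells

logging.getLogger("ecstrata").setLevel(logging.WARNING)


def run_pipeline(seed: int = 1, louvain_seed: int = 1):
    """simulate → qc → normalize → cluster on the standard benchmark."""
    cm, meta, truth = synth_data.simulate_counts(synth_data.benchmark_config(seed))
    filtered, report = qc.apply_qc(cm)
    kept = [cm.cell_ids.index(c) for c in filtered.cell_ids]
    lm, factors = normalize.normalize_counts(filtered)
    labels, embedding, n_pcs = cluster_cells(lm, seed=louvain_seed)
    return {
        "counts": cm,
        "filtered": filtered,
        "qc_report": report,
        "truth": truth,
        "kept_cells": np.asarray(kept),
        "log_matrix": lm,
        "size_factors": factors,
        "labels": labels,
        "embedding": embedding,
        "n_pcs": n_pcs,
    }


@pytest.fixture(scope="session")
def benchmark_pipeline():
    return run_pipeline()


@pytest.fixture(scope="session")
def benchmark_de(benchmark_pipeline):
    from ecstrata.markers import load_dissociation_genes, pairwise_de

    bp = benchmark_pipeline
    truth_labels = bp["truth"].true_cluster[bp["kept_cells"]]
    return pairwise_de(
        bp["log_matrix"], truth_labels, exclusion_list=load_dissociation_genes()
    )
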
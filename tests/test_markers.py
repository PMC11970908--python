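"""Pairwise DE, max-FDR filtering, rank products and module scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ecstrata import synth_data as sd
from ecstrata.errors import ValidationError
from ecstrata.io_core import GeneSet, LogMatrix
from ecstrata.markers import (
    DETable,
    assign_cell_types,
    de_by_max_fdr,
    module_score,
    pairwise_de,
    rank_product_signatures,
    score_gene_sets,
)


def lm_from(genes_by_cells, gene_ids=None):
    x = np.asarray(genes_by_cells, dtype=float)
    return LogMatrix(
        sp.csr_matrix(x),
        gene_ids or [f"g{i}" for i in range(x.shape[0])],
        [f"c{i}" for i in range(x.shape[1])],
    )


class TestPairwiseDe:
    def test_constant_gene_max_q_one(self):
        rng = np.random.default_rng(0)
        x = rng.random((5, 60))
        x[0] = 1.0  # identical everywhere
        labels = np.repeat([0, 1, 2], 20)
        t = pairwise_de(lm_from(x), labels)
        sub = t.summary[t.summary.gene == "g0"]
        assert (sub.max_q == 1.0).all()

    def test_excluded_gene_absent(self):
        rng = np.random.default_rng(1)
        x = rng.random((4, 40))
        t = pairwise_de(
            lm_from(x), np.repeat([0, 1], 20),
            exclusion_list=GeneSet("excl", frozenset({"g2"})),
        )
        assert "g2" not in set(t.records.gene)
        assert "g2" not in set(t.summary.gene)

    def test_pair_symmetry_under_relabeling(self):
        rng = np.random.default_rng(2)
        x = rng.random((6, 60))
        labels = np.repeat([0, 1, 2], 20)
        t1 = pairwise_de(lm_from(x), labels)
        t2 = pairwise_de(lm_from(x), 2 - labels)  # swap cluster identities
        r1 = t1.records.set_index(["gene", "cluster_a", "cluster_b"])
        for (g, a, b), row in r1.iterrows():
            # pair (a,b) under the flip becomes (2-b, 2-a)
            row2 = t2.records[
                (t2.records.gene == g)
                & (t2.records.cluster_a == 2 - b)
                & (t2.records.cluster_b == 2 - a)
            ].iloc[0]
            assert row2.p == pytest.approx(row.p)
            assert row2.q == pytest.approx(row.q)
            assert row2.log2fc == pytest.approx(-row.log2fc)

    def test_small_cluster_rejected(self):
        x = np.random.default_rng(3).random((4, 21))
        labels = np.array([0] * 20 + [1])
        with pytest.raises(ValidationError, match="1"):
            pairwise_de(lm_from(x), labels)

    def test_planted_markers_highly_significant(self, benchmark_pipeline,
                                                benchmark_de):
        bp = benchmark_pipeline
        truth = bp["truth"]
        summary = benchmark_de.summary
        for k in range(6):
            sub = summary[(summary.cluster == k)
                          & summary.gene.isin(truth.true_markers[k])]
            assert (sub.max_q < 1e-10).all()


class TestDeByMaxFdr:
    def test_vacuous_threshold_passes_every_gene(self):
        rng = np.random.default_rng(4)
        x = rng.random((5, 40))
        t = pairwise_de(lm_from(x), np.repeat([0, 1], 20))
        de = de_by_max_fdr(t, threshold=1.1, min_log2fc=-np.inf)
        assert de[0] | de[1] >= set(t.summary.gene)

    def test_monotone_in_threshold(self, benchmark_de):
        loose = de_by_max_fdr(benchmark_de, threshold=1e-5)
        tight = de_by_max_fdr(benchmark_de, threshold=1e-15)
        for k in loose:
            assert tight[k] <= loose[k]

    def test_empty_table(self):
        t = DETable(
            records=pd.DataFrame(
                columns=["gene", "cluster_a", "cluster_b", "p", "q", "log2fc"]
            ),
            summary=pd.DataFrame(
                columns=["gene", "cluster", "max_q", "min_log2fc", "n_comparisons"]
            ),
            clusters=(0, 1),
        )
        de = de_by_max_fdr(t)
        assert de == {0: frozenset(), 1: frozenset()}

    def test_marker_recovery_on_benchmark(self, benchmark_pipeline, benchmark_de):
        truth = benchmark_pipeline["truth"]
        de = de_by_max_fdr(benchmark_de, threshold=1e-10, min_log2fc=2.0)
        tp = fp = fn = 0
        for k in range(6):
            found, true = de[k], truth.true_markers[k]
            tp += len(found & true)
            fp += len(found - true)
            fn += len(true - found)
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9


def make_de_table(q_by_comparison, cluster=0, others=(1, 2)):
    """Assemble a DETable for one cluster from per-comparison q-values."""
    genes = list(q_by_comparison[0].keys())
    records = []
    for other, qmap in zip(others, q_by_comparison):
        a, b = min(cluster, other), max(cluster, other)
        for g in genes:
            records.append(
                {"gene": g, "cluster_a": a, "cluster_b": b, "p": qmap[g],
                 "q": qmap[g], "log2fc": 1.0}
            )
    summary = [
        {"gene": g, "cluster": cluster,
         "max_q": max(qmap[g] for qmap in q_by_comparison),
         "min_log2fc": 1.0, "n_comparisons": len(others)}
        for g in genes
    ]
    return DETable(
        records=pd.DataFrame(records),
        summary=pd.DataFrame(summary),
        clusters=tuple([cluster, *others]),
    )


class TestRankProduct:
    def test_top_ranked_gene_hits_floor(self):
        # 50 candidates, 3 comparisons: tie probability (1/50)^3 is
        # negligible against 1/(n_perm+1)
        genes = [f"g{i}" for i in range(50)]
        qmaps = []
        rng = np.random.default_rng(5)
        for _ in range(3):
            qs = np.sort(rng.uniform(1e-40, 1e-12, size=50))
            qmaps.append({g: q for g, q in zip(genes, qs)})
        t = make_de_table(qmaps, others=(1, 2, 3))
        entry = rank_product_signatures(t, 0, n_perm=2000, seed=0)
        row = entry.table[entry.table.gene == "g0"].iloc[0]
        assert row.rank_product == pytest.approx(1.0)
        assert row.p == pytest.approx(1 / 2001)

    def test_permutation_p_matches_enumeration(self):
        # 2 comparisons x 4 candidate genes: exact null by enumerating
        # the 4^2 equally likely (rank, rank) pairs per gene
        genes = ["a", "b", "c", "d"]
        q1 = {"a": 1e-30, "b": 1e-25, "c": 1e-20, "d": 1e-15}
        q2 = {"a": 1e-18, "b": 1e-30, "c": 1e-22, "d": 1e-12}
        t = make_de_table([q1, q2])
        n_perm = 10000
        entry = rank_product_signatures(t, 0, n_perm=n_perm, seed=1)
        ranks1 = {g: r for r, g in enumerate(sorted(genes, key=q1.get), 1)}
        ranks2 = {g: r for r, g in enumerate(sorted(genes, key=q2.get), 1)}
        for g in genes:
            obs = ranks1[g] * ranks2[g]
            exact = np.mean(
                [r1 * r2 <= obs for r1, r2 in itertools.product(range(1, 5),
                                                                repeat=2)]
            )
            got = entry.table.set_index("gene").loc[g, "p"]
            assert abs(got - exact) <= 2 / np.sqrt(n_perm)

    def test_all_tied_fdrs_give_equal_rp_uniformish_p(self):
        genes = [f"g{i}" for i in range(5)]
        q = {g: 1e-20 for g in genes}
        t = make_de_table([q, q])
        entry = rank_product_signatures(t, 0, n_perm=500, seed=2)
        assert entry.table.rank_product.nunique() == 1
        assert (entry.table.p > 0.5).all()

    def test_no_candidates_empty_with_warning(self):
        q = {"a": 0.5, "b": 0.9}
        t = make_de_table([q, q])
        entry = rank_product_signatures(t, 0, n_perm=100, seed=0)
        assert len(entry.table) == 0

    def test_false_positive_control_on_null_data(self):
        """Without planted markers, no gene should beat the max-FDR 1e-10
        bar in almost all seeds."""
        failures = 0
        for seed in range(50):
            cfg = sd.SynthConfig(
                n_clusters=2, cells_per_cluster=100, n_genes=300,
                n_marker_genes_per_cluster=0, marker_log2fc=0.0,
                doublet_rate=0.0, gradient_genes=0, seed=seed,
            )
            cm, _, truth = sd.simulate_counts(cfg)
            x = np.log2(np.asarray(cm.values.todense()) + 1.0)
            t = pairwise_de(lm_from(x, gene_ids=list(cm.gene_ids)),
                            truth.true_cluster)
            de = de_by_max_fdr(t, threshold=1e-10)
            if any(de.values()):
                failures += 1
        assert failures <= 2  # >= 95% of seeds clean


class TestModuleScore:
    def test_whole_gene_universe_scores_zero(self):
        rng = np.random.default_rng(6)
        lm = lm_from(rng.random((8, 10)))
        gs = GeneSet("all", frozenset(lm.gene_ids))
        assert module_score(lm, gs) == pytest.approx(np.zeros(10), abs=1e-12)

    def test_plug_in_formula(self):
        # cell expresses only the s=2 set genes at v=3 among G=6 genes
        x = np.zeros((6, 1))
        x[:2, 0] = 3.0
        lm = lm_from(x)
        gs = GeneSet("s", frozenset({"g0", "g1"}))
        expected = 3.0 - 3.0 * 2 / 6
        assert module_score(lm, gs)[0] == pytest.approx(expected)

    def test_absent_set_rejected(self):
        lm = lm_from(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            module_score(lm, GeneSet("ghost", frozenset({"nope"})))


class TestAssignCellTypes:
    def test_argmax_assignment_and_tie_rule(self):
        scores = pd.DataFrame(
            {"A": [2.0, 1.0, 0.5], "B": [-1.0, 3.0, 0.5]},
            index=["c0", "c1", "c2"],
        )
        table = assign_cell_types(scores)
        assert table.assigned.tolist() == ["A", "B", "unassigned"]

    def test_planted_types_recovered_with_z_validation(self, benchmark_pipeline):
        bp = benchmark_pipeline
        truth = bp["truth"]
        gene_sets = [
            GeneSet(f"type{k}", truth.true_markers[k]) for k in range(6)
        ]
        scores = score_gene_sets(bp["log_matrix"], gene_sets)
        table = assign_cell_types(scores, lm=bp["log_matrix"], gene_sets=gene_sets)
        truth_types = [f"type{k}" for k in truth.true_cluster[bp["kept_cells"]]]
        acc = np.mean(np.asarray(truth_types) == table.assigned.to_numpy())
        assert acc >= 0.95
        # z-validation diagonal dominates
        z = table.z_validation
        for t in z.index:
            assert z.loc[t, t] == pytest.approx(z.loc[t].max())

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            assign_cell_types(pd.DataFrame({"A": [1.0]}))
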
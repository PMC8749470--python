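import numpy as np
import pytest

from receptornet.clustering import (
    ClusterAssignment,
    CorrelationMatrix,
    agglomerative_cluster,
    cluster_geneset_enrichment,
    correlation_matrix,
    find_seed_cluster,
)
from receptornet.types import CellTypeLabels, ValidationError
from .conftest import make_expr
from .test_enrichment import tail_by_enumeration


def corr_from(genes, matrix):
    return CorrelationMatrix(genes=list(genes), matrix=np.asarray(matrix, float),
                             method="spearman", cell_scope="all")


class TestCorrelationMatrix:
    def test_identical_vectors_correlate_perfectly(self):
        expr = make_expr(np.array([[1, 1], [2, 2], [3, 3]], dtype=float))
        corr = correlation_matrix(expr, expr.gene_ids)
        assert corr.matrix[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_anticorrelate(self):
        expr = make_expr(np.array([[1, 3], [2, 2], [3, 1]], dtype=float))
        corr = correlation_matrix(expr, expr.gene_ids)
        assert corr.matrix[0, 1] == pytest.approx(-1.0)

    def test_spearman_single_swap(self):
        # ranks (1,2,3) vs (1,3,2): rho = 1 - 6*2/(3*8) = 0.5
        expr = make_expr(np.array([[1, 1], [2, 3], [3, 2]], dtype=float))
        corr = correlation_matrix(expr, expr.gene_ids)
        assert corr.matrix[0, 1] == pytest.approx(0.5)

    def test_zero_variance_gene_flagged_with_zero_correlation(self):
        expr = make_expr(np.array([[1, 5], [2, 5], [3, 5]], dtype=float))
        corr = correlation_matrix(expr, expr.gene_ids)
        assert corr.zero_variance_genes == ["GENE1"]
        assert corr.matrix[0, 1] == 0.0
        assert corr.matrix[1, 1] == 1.0

    def test_target_scope_restricts_cells(self):
        values = np.array(
            [[1, 1], [2, 2], [3, 3], [1, 3], [2, 2], [3, 1]], dtype=float
        )
        expr = make_expr(values)
        labels = CellTypeLabels(labels={
            c: ("ec" if i < 3 else "other") for i, c in enumerate(expr.cell_ids)
        })
        corr = correlation_matrix(expr, expr.gene_ids, labels=labels,
                                  cell_scope="target_type", target_type="ec")
        assert corr.matrix[0, 1] == pytest.approx(1.0)

    def test_fewer_than_two_genes_rejected(self):
        expr = make_expr(np.ones((3, 2)))
        with pytest.raises(ValidationError):
            correlation_matrix(expr, ["GENE0"])

    def test_distance_bounded(self):
        rng = np.random.default_rng(3)
        expr = make_expr(rng.random((20, 6)))
        corr = correlation_matrix(expr, expr.gene_ids)
        d = 1 - corr.matrix
        assert np.all(d >= -1e-12) and np.all(d <= 2 + 1e-12)


class TestAgglomerativeCluster:
    def test_separable_blocks_recovered(self):
        genes = ["A", "B", "C", "D"]
        m = np.array([
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 1, 1],
        ], dtype=float)
        a = agglomerative_cluster(corr_from(genes, m), k=2)
        assert a.assignment["A"] == a.assignment["B"]
        assert a.assignment["C"] == a.assignment["D"]
        assert a.assignment["A"] != a.assignment["C"]

    def test_k_equals_gene_count_gives_singletons(self):
        genes = ["A", "B", "C"]
        m = np.eye(3)
        a = agglomerative_cluster(corr_from(genes, m), k=3)
        assert sorted(a.assignment.values()) == [1, 2, 3]

    def test_k_beyond_gene_count_rejected(self):
        with pytest.raises(ValidationError):
            agglomerative_cluster(corr_from(["A", "B"], np.eye(2)), k=3)

    def test_merge_order_matches_hand_average_linkage_trace(self):
        # corr: AB=.9 CD=.8 AC=.1 AD=0 BC=.2 BD=.1
        # d:    AB=.1 CD=.2 AC=.9 AD=1 BC=.8 BD=.9
        # average linkage: merge AB at .1; then d(AB,C)=.85, d(AB,D)=.95,
        # d(C,D)=.2 -> merge CD at .2; final merge at .9
        genes = ["A", "B", "C", "D"]
        m = np.array([
            [1.0, 0.9, 0.1, 0.0],
            [0.9, 1.0, 0.2, 0.1],
            [0.1, 0.2, 1.0, 0.8],
            [0.0, 0.1, 0.8, 1.0],
        ])
        at3 = agglomerative_cluster(corr_from(genes, m), k=3)
        assert at3.assignment["A"] == at3.assignment["B"]
        assert at3.assignment["C"] != at3.assignment["D"]
        at2 = agglomerative_cluster(corr_from(genes, m), k=2)
        assert at2.assignment["C"] == at2.assignment["D"]
        assert at2.assignment["A"] != at2.assignment["C"]

    def test_partitions_nest_as_k_decreases(self):
        rng = np.random.default_rng(9)
        n = 12
        x = rng.random((n, n))
        m = np.corrcoef(x)
        corr = corr_from([f"g{i}" for i in range(n)], m)
        prev = agglomerative_cluster(corr, k=n).assignment
        for k in range(n - 1, 0, -1):
            cur = agglomerative_cluster(corr, k=k).assignment
            # every previous cluster maps into exactly one current cluster
            mapping = {}
            for g in prev:
                mapping.setdefault(prev[g], set()).add(cur[g])
            assert all(len(v) == 1 for v in mapping.values())
            prev = cur

    def test_gene_order_permutation_preserves_partition(self):
        rng = np.random.default_rng(4)
        n = 10
        base = rng.random((30, n))
        m = np.corrcoef(base, rowvar=False)
        genes = [f"g{i}" for i in range(n)]
        a = agglomerative_cluster(corr_from(genes, m), k=3).assignment
        perm = rng.permutation(n)
        m2 = m[np.ix_(perm, perm)]
        genes2 = [genes[i] for i in perm]
        b = agglomerative_cluster(corr_from(genes2, m2), k=3).assignment
        # same partition up to relabeling
        pairs_a = {(g, h) for g in genes for h in genes if a[g] == a[h]}
        pairs_b = {(g, h) for g in genes for h in genes if b[g] == b[h]}
        assert pairs_a == pairs_b


class TestSeedCluster:
    def _assignment(self):
        return ClusterAssignment(
            assignment={"KDR": 3, "FLT1": 1, "LIFR": 3, "X": 2}, k=3,
            linkage="average",
        )

    def test_single_seed_found(self):
        a = self._assignment()
        assert find_seed_cluster(a, ["KDR"]) == 3

    def test_split_seeds_prefer_first(self, caplog):
        a = self._assignment()
        with caplog.at_level("WARNING", logger="receptornet.clustering"):
            assert find_seed_cluster(a, ["KDR", "FLT1"]) == 3
        assert any("split" in r.message for r in caplog.records)

    def test_majority_wins_when_seeds_split(self):
        a = ClusterAssignment(
            assignment={"S1": 1, "S2": 2, "S3": 2}, k=2, linkage="average"
        )
        assert find_seed_cluster(a, ["S1", "S2", "S3"]) == 2

    def test_absent_seeds_rejected(self):
        with pytest.raises(ValidationError):
            find_seed_cluster(self._assignment(), ["NOPE"])


class TestClusterGenesetEnrichment:
    def test_matches_enumeration(self):
        # 18-gene cluster of a 60-gene universe; set covers 20; overlap 15
        genes = [f"G{i}" for i in range(60)]
        assignment = ClusterAssignment(
            assignment={g: (1 if i < 18 else 2) for i, g in enumerate(genes)},
            k=2, linkage="average",
        )
        gene_set = set(genes[:15]) | set(genes[30:35])
        res = cluster_geneset_enrichment(assignment, 1, gene_set, "S")
        assert res.overlap == 15
        assert res.p_value == pytest.approx(
            tail_by_enumeration(15, 20, 18, 60), rel=1e-10
        )

    def test_cluster_equal_to_universe_is_certain(self):
        genes = ["a", "b", "c"]
        assignment = ClusterAssignment(
            assignment={g.upper(): 1 for g in genes}, k=1, linkage="average"
        )
        assert cluster_geneset_enrichment(assignment, 1, {"A", "B"}).p_value == 1.0

    def test_zero_overlap_is_certain(self):
        assignment = ClusterAssignment(
            assignment={"A": 1, "B": 2, "C": 2}, k=2, linkage="average"
        )
        assert cluster_geneset_enrichment(assignment, 1, {"B", "C"}).p_value == 1.0

    def test_disjoint_set_rejected(self):
        assignment = ClusterAssignment(
            assignment={"A": 1, "B": 2}, k=2, linkage="average"
        )
        with pytest.raises(ValidationError):
            cluster_geneset_enrichment(assignment, 1, {"ZZZ"})

    def test_explicit_universe_policy(self):
        assignment = ClusterAssignment(
            assignment={"A": 1, "B": 1, "C": 2}, k=2, linkage="average"
        )
        universe = ["A", "B", "C", "D", "E", "F"]
        res = cluster_geneset_enrichment(assignment, 1, {"A", "B", "D"},
                                         universe=universe)
        assert res.universe_size == 6
        assert res.set_size_in_universe == 3
        assert res.p_value == pytest.approx(
            tail_by_enumeration(2, 3, 2, 6), rel=1e-10
        )
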
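import numpy as np
import pytest
from _oracles import brute_components, brute_similarities, random_partition_set

from sceve.base_clustering import PartitionSet
from sceve.consensus import (
    BaseClusterVertex,
    build_graph,
    components,
    consensus_step,
    majority,
    pairwise_similarities,
    robustness_threshold,
    vertices_from_partitions,
)


def make_ps(assignments: dict) -> PartitionSet:
    """assignments: method -> label list over cells c0, c1, ..."""
    n = len(next(iter(assignments.values())))
    ps = PartitionSet(pool_cell_ids=[f"c{i}" for i in range(n)])
    for method, labels in assignments.items():
        ps.add(method, np.asarray(labels))
    return ps


class TestPairwiseSimilarity:
    def test_identical_clusters_score_one(self):
        ps = make_ps({"A": [0, 0, 1, 1], "B": [5, 5, 6, 6]})
        edges = pairwise_similarities(ps)
        assert all(e.s == 1.0 for e in edges)
        assert len(edges) == 2

    def test_disjoint_clusters_have_no_edge(self):
        ps = make_ps({"A": [0, 0, 1, 1], "B": [0, 0, 1, 1]})
        edges = pairwise_similarities(ps)
        keys = {(e.x.label, e.y.label) for e in edges}
        assert ("0", "1") not in keys and ("1", "0") not in keys

    def test_hand_enumerated_overlap(self):
        # x = {c0,c1} in A; y = {c0,c1,c2,c3} in B -> s = min(2/2, 2/4) = 0.5
        ps = make_ps({"A": [0, 0, 1, 1], "B": [0, 0, 0, 0]})
        edges = pairwise_similarities(ps)
        by_x = {e.x.label: e.s for e in edges}
        assert by_x["0"] == pytest.approx(0.5)
        assert by_x["1"] == pytest.approx(0.5)

    def test_no_edges_within_a_method(self):
        ps = make_ps({"A": [0, 0, 1, 1], "B": [0, 1, 0, 1]})
        assert all(e.x.method != e.y.method for e in pairwise_similarities(ps))


class TestBuildGraph:
    def test_strict_threshold_boundary(self):
        ps = make_ps({"A": [0, 0, 1, 1], "B": [0, 0, 0, 0]})  # all s = 0.5
        graph = build_graph(pairwise_similarities(ps), s_lim=0.5)
        assert graph.number_of_edges() == 0

    def test_edge_above_threshold_retained(self):
        ps = make_ps({"A": [0, 0, 0, 0, 1], "B": [0, 0, 0, 1, 1]})  # s(x0,y0)=0.75
        graph = build_graph(pairwise_similarities(ps), s_lim=0.5)
        retained = {(u.key, v.key) for u, v in graph.edges}
        assert any("0" == u[1] and "0" == v[1] for u, v in retained)

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        ps = random_partition_set(rng, 50, 3)
        edges = pairwise_similarities(ps)
        for s_lim in (0.3, 0.5, 0.7):
            graph = build_graph(edges, s_lim, vertices=vertices_from_partitions(ps))
            got = {frozenset((u.key, v.key)) for u, v in graph.edges}
            want = {
                frozenset((e.x.key, e.y.key)) for e in edges if e.s > s_lim
            }
            assert got == want

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_graph([], s_lim=1.0)


class TestComponents:
    def test_full_agreement_has_robustness_one(self):
        ps = make_ps({m: [0, 0, 1, 1] for m in "ABCD"})
        graph = build_graph(pairwise_similarities(ps), 0.5)
        comps = components(graph, 4)
        assert len(comps) == 2
        for comp in comps:
            assert len(comp.strong_edges) == 6
            assert comp.robustness == pytest.approx(1.0)

    def test_two_vertex_component_robustness(self):
        # one shared edge with s = 0.6, M = 4 -> R = 0.6/6 = 0.1
        ps = make_ps({
            "A": [0] * 10 + [1] * 10,
            "B": [0] * 6 + [1] * 14,  # shared 6; s = min(6/10, 6/10) = 0.6
        })
        graph = build_graph(pairwise_similarities(ps), 0.5)
        comps = components(graph, 4)
        comp = next(c for c in comps if ("A", "0") in {v.key for v in c.vertices})
        assert len(comp.vertices) == 2
        assert comp.robustness == pytest.approx(0.6 / 6)

    def test_singleton_component(self):
        vertex = BaseClusterVertex("A", "0", frozenset({"c0", "c1"}))
        graph = build_graph([], 0.5, vertices=[vertex])
        comps = components(graph, 4)
        assert len(comps) == 1
        assert comps[0].robustness == 0.0
        assert comps[0].core_cells == vertex.cells

    def test_same_method_twice_gives_empty_core(self):
        # A's two clusters both strongly overlap B's big cluster, chaining
        # them into one component whose intersection is empty
        ps = make_ps({"A": [0, 0, 0, 1, 1], "B": [0, 0, 0, 0, 0]})
        graph = build_graph(pairwise_similarities(ps), 0.3)
        comps = components(graph, 2)
        big = max(comps, key=lambda c: len(c.vertices))
        methods = [v.method for v in big.vertices]
        assert methods.count("A") == 2
        assert big.core_cells == frozenset()


class TestRobustnessThreshold:
    def test_published_default(self):
        assert robustness_threshold(0.5, 3, 4) == pytest.approx(0.25)

    def test_full_agreement_limit(self):
        for n in (2, 3, 4, 7):
            assert robustness_threshold(1.0, n, n) == pytest.approx(1.0)

    def test_hand_computed_small_ensemble(self):
        assert robustness_threshold(0.5, 2, 3) == pytest.approx(0.5 / 3)

    def test_majority_default(self):
        assert majority(4) == 3
        assert majority(3) == 2
        assert robustness_threshold(0.5, n_methods=4) == pytest.approx(0.25)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            robustness_threshold(0.5, 5, 4)


def three_of_four_ps():
    """Three of four methods agree exactly on {c0,c1}; the fourth differs."""
    return make_ps({
        "A": [0, 0, 1, 1, 1, 1],
        "B": [0, 0, 1, 1, 1, 1],
        "C": [0, 0, 1, 1, 1, 1],
        "D": [0, 1, 1, 1, 1, 1],
    })


class TestConsensusStep:
    def test_perfect_agreement_two_clusters(self):
        ps = make_ps({m: [0, 0, 0, 1, 1, 1] for m in "ABCD"})
        out = consensus_step(ps, 0.5, 0.25)
        assert len(out.robust_clusters) == 2
        assert all(rc.robustness == pytest.approx(1.0) for rc in out.robust_clusters)
        assert out.leftover_cells == frozenset()

    def test_low_robustness_component_rejected(self):
        ps = make_ps({
            "A": [0] * 10 + [1] * 10,
            "B": [0] * 6 + [1] * 14,
            "C": list(range(20)),  # all singletons: no strong edges
            "D": list(range(20)),
        })
        out = consensus_step(ps, 0.5, 0.25)  # best component R = 0.1
        assert out.robust_clusters == []
        assert out.leftover_cells == frozenset(ps.pool_cell_ids)

    def test_three_of_four_agreement_accepted(self):
        out = consensus_step(three_of_four_ps(), 0.5, 0.25)
        small = [rc for rc in out.robust_clusters if rc.cells == frozenset({"c0", "c1"})]
        assert len(small) == 1
        assert small[0].robustness == pytest.approx(3 / 6)
        assert small[0].methods == ["A", "B", "C"]

    def test_leftover_robustness_is_zero(self):
        out = consensus_step(three_of_four_ps(), 0.5, 0.55)
        assert out.leftover_robustness == 0.0
        assert out.leftover_cells  # D's disagreement leaves cells behind

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ps = random_partition_set(rng, int(rng.integers(10, 120)), int(rng.integers(2, 6)))
            out = consensus_step(ps, 0.5, 0.25)
            claimed = [rc.cells for rc in out.robust_clusters] + [out.leftover_cells]
            union = frozenset().union(*claimed)
            assert union == frozenset(ps.pool_cell_ids)
            assert sum(len(c) for c in claimed) == len(ps.pool_cell_ids)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ps = random_partition_set(rng, 80, 4)
            edges = pairwise_similarities(ps)
            strong_counts = [
                build_graph(edges, s, vertices_from_partitions(ps)).number_of_edges()
                for s in (0.3, 0.5, 0.7)
            ]
            assert strong_counts == sorted(strong_counts, reverse=True)
            n_robust = [
                len(consensus_step(ps, 0.5, r).robust_clusters) for r in (0.1, 0.25, 0.5)
            ]
            assert n_robust == sorted(n_robust, reverse=True)

    def test_invariance_to_method_order_and_label_names(self):
        rng = np.random.default_rng(5)
        ps = random_partition_set(rng, 60, 4)
        out = consensus_step(ps, 0.5, 0.25)
        renamed = PartitionSet(pool_cell_ids=ps.pool_cell_ids)
        for method in reversed(sorted(ps.partitions)):
            labels = ps.partitions[method]
            renamed.add(method, np.asarray([f"x{hash((method, l)) % 97}_{l}" for l in labels]))
        out2 = consensus_step(renamed, 0.5, 0.25)
        assert {rc.cells for rc in out.robust_clusters} == {rc.cells for rc in out2.robust_clusters}
        assert out.leftover_cells == out2.leftover_cells


class TestOracleEquivalence:
    def test_edges_and_components_match_brute_force(self):
        """Similarities and component membership vs naive counting/union-find."""
        rng = np.random.default_rng(12345)
        for _ in range(30):
            n_cells = int(rng.integers(5, 200))
            n_methods = int(rng.integers(2, 6))
            ps = random_partition_set(rng, n_cells, n_methods)
            edges = pairwise_similarities(ps)
            expected = brute_similarities(ps)
            got = {frozenset((e.x.key, e.y.key)): e.s for e in edges}
            assert got == pytest.approx(expected)

            s_lim = float(rng.uniform(0.2, 0.8))
            graph = build_graph(edges, s_lim, vertices=vertices_from_partitions(ps))
            comps = components(graph, n_methods)
            vertex_keys = [v.key for v in vertices_from_partitions(ps)]
            strong = [
                (e.x.key, e.y.key) for e in edges if e.s > s_lim
            ]
            expected_comps = brute_components(vertex_keys, strong)
            got_comps = {frozenset(v.key for v in c.vertices) for c in comps}
            assert got_comps == expected_comps
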
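import networkx as nx
import numpy as np
import pytest

from cpirex.apg_kernel import (
    APGFeatureMatrix,
    APGParams,
    DegenerateInstanceError,
    all_paths_matrix,
    apg_kernel_matrix,
    apg_kernel_value,
    build_weighted_graph,
    feature_matrix,
    shortest_path_edges,
    vertex_labels,
)
from cpirex.corpus import CandidatePair
from cpirex.preprocess import (
    BlindedInstance,
    DependencyEdge,
    EntityTokenSpan,
    Token,
)

from conftest import make_instance


def _tok(i, surface, pos="NN"):
    return Token(
        index=i, surface=surface, char_start=0, char_end=len(surface), pos=pos,
        is_capitalized=surface[:1].isupper(), is_punct=False, is_numeral=False,
    )


def chain_instance(surfaces, comp_index, prot_index, pair_id="p0"):
    tokens = [_tok(i, s) for i, s in enumerate(surfaces)]
    edges = [DependencyEdge(i, i + 1, "next") for i in range(len(surfaces) - 1)]
    return BlindedInstance(
        pair=CandidatePair(pair_id, "e0", "e1"),
        doc_id="d0",
        tokens=tokens,
        edges=edges,
        compound_index=comp_index,
        protein_index=prot_index,
    )


def span(i):
    return EntityTokenSpan("e", i, i)


class TestShortestPathEdges:
    def test_unique_chain_path(self):
        edges = [DependencyEdge(i, i + 1, "next") for i in range(3)]
        assert shortest_path_edges(edges, span(0), span(3)) == {
            (0, 1), (1, 2), (2, 3)
        }

    def test_diamond_returns_both_shortest_paths(self):
        edges = [
            DependencyEdge(0, 1, "a"), DependencyEdge(1, 3, "b"),
            DependencyEdge(0, 2, "c"), DependencyEdge(2, 3, "d"),
        ]
        assert shortest_path_edges(edges, span(0), span(3)) == {
            (0, 1), (1, 3), (0, 2), (2, 3)
        }

    def test_disconnected_components_give_empty_set(self):
        edges = [DependencyEdge(0, 1, "a"), DependencyEdge(2, 3, "b")]
        assert shortest_path_edges(edges, span(0), span(3)) == set()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        graph = nx.gnp_random_graph(n, 0.4, seed=seed)
        edges = [DependencyEdge(u, v, "x") for u, v in graph.edges]
        s1, s2 = span(0), span(n - 1)
        got = shortest_path_edges(edges, s1, s2)
        # oracle: enumerate all simple paths, keep minimal length
        if nx.has_path(graph, 0, n - 1):
            paths = list(nx.all_simple_paths(graph, 0, n - 1))
            dmin = min(len(p) - 1 for p in paths)
            expected = {
                (min(u, v), max(u, v))
                for p in paths if len(p) - 1 == dmin
                for u, v in zip(p, p[1:])
            }
        else:
            expected = set()
        assert got == expected


class TestBuildWeightedGraph:
    def test_whole_chain_is_shortest_path(self):
        inst = chain_instance(["COMPOUND_C", "binds", "PROTEIN_C"], 0, 2)
        params = APGParams(w_sp=0.9, w_other=0.3)
        graph, alloc = build_weighted_graph(inst, params)
        nz = graph.W[graph.W > 0]
        assert len(nz) == 4  # 2 undirected edges, both orientations
        assert np.allclose(nz, 0.9)

    def test_off_path_edges_get_background_weight(self):
        inst = chain_instance(["COMPOUND_C", "x", "PROTEIN_C", "y"], 0, 2)
        graph, _ = build_weighted_graph(inst, APGParams())
        assert graph.W[0, 1] == graph.W[1, 2] == 0.9
        assert graph.W[2, 3] == graph.W[3, 2] == 0.3

    def test_vertex_label_set(self):
        inst = chain_instance(["COMPOUND_C", "inhibits", "PROTEIN_C"], 0, 2)
        inst.tokens[1] = _tok(1, "inhibits", pos="VBZ")
        assert vertex_labels(inst, 1) == {"inhibits", "pos:VBZ", "dep:next"}
        # placeholders keep their uppercase placeholder label
        assert "COMPOUND_C" in vertex_labels(inst, 0)

    def test_single_vertex_is_degenerate(self):
        inst = chain_instance(["COMPOUND_C"], 0, 0)
        with pytest.raises(DegenerateInstanceError):
            build_weighted_graph(inst, APGParams())


class TestAllPathsMatrix:
    def test_single_edge_has_no_longer_walks(self):
        W = np.array([[0.0, 0.5], [0.0, 0.0]])
        M, truncated = all_paths_matrix(W)
        assert not truncated
        assert np.allclose(M, W)

    def test_closed_form_equals_truncated_series(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(2, 9)
            W = rng.random((n, n)) * rng.integers(0, 2, (n, n))
            rho = max(abs(np.linalg.eigvals(W)))
            if rho >= 0.9:
                W = W * (0.8 / rho)  # keep the series safely convergent
            M, truncated = all_paths_matrix(W)
            assert not truncated
            series = np.zeros_like(W)
            power = np.eye(W.shape[0])
            for _ in range(200):
                power = power @ W
                series += power
            assert np.allclose(M, series, atol=1e-9)

    def test_divergent_series_is_truncated_and_flagged(self):
        W = np.array([[1.0]])
        M, truncated = all_paths_matrix(W, d_max=5)
        assert truncated
        assert M[0, 0] == pytest.approx(5.0)  # 5 unit self-loops

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            all_paths_matrix(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            all_paths_matrix(np.array([[-0.1]]))


class TestFeatureMatrix:
    def test_identity_allocation_returns_path_matrix(self):
        from cpirex.apg_kernel import LabelAllocation

        M = np.array([[0.0, 0.4], [0.1, 0.0]])
        alloc = LabelAllocation(L=np.eye(2), labels=["a", "b"])
        assert np.allclose(feature_matrix(alloc, M).G, M)

    def test_single_edge_hand_enumeration(self):
        from cpirex.apg_kernel import LabelAllocation

        M = np.array([[0.0, 0.5], [0.0, 0.0]])
        alloc = LabelAllocation(
            L=np.array([[1.0, 0.0], [0.0, 1.0]]), labels=["x", "y"]
        )
        G = feature_matrix(alloc, M).G
        assert G[0, 1] == pytest.approx(0.5)
        assert np.count_nonzero(G) == 1

    def test_multi_label_vertex_duplicates_contributions(self):
        from cpirex.apg_kernel import LabelAllocation

        M = np.array([[0.0, 0.5], [0.0, 0.0]])
        # vertex 0 carries labels x and z
        alloc = LabelAllocation(
            L=np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]), labels=["x", "y", "z"]
        )
        G = feature_matrix(alloc, M).G
        assert G[0, 1] == G[2, 1] == pytest.approx(0.5)
        # column sums of L explain the total mass
        assert G.sum() == pytest.approx(alloc.L.sum(axis=0)[0] * 0.5 * 2)


class TestKernelValue:
    def test_identical_identity_matrices(self):
        fm = APGFeatureMatrix(G=np.eye(2), labels=["a", "b"])
        assert apg_kernel_value(fm, fm) == pytest.approx(2.0)

    def test_disjoint_alphabets_give_zero(self):
        fm1 = APGFeatureMatrix(G=np.ones((1, 1)), labels=["a"])
        fm2 = APGFeatureMatrix(G=np.ones((1, 1)), labels=["b"])
        assert apg_kernel_value(fm1, fm2) == 0.0

    def test_elementwise_multiply_accumulate(self):
        fm1 = APGFeatureMatrix(G=np.array([[1.0, 2.0], [3.0, 4.0]]), labels=["a", "b"])
        fm2 = APGFeatureMatrix(G=np.ones((2, 2)), labels=["a", "b"])
        assert apg_kernel_value(fm1, fm2) == pytest.approx(10.0)


def _bruteforce_dag_feature_matrix(W, label_sets):
    """Oracle: enumerate every directed path in a DAG and pool by labels."""
    n = W.shape[0]
    totals = {}

    def extend(path, weight):
        u = path[-1]
        for v in range(n):
            if W[u, v] > 0:
                w2 = weight * W[u, v]
                for la in label_sets[path[0]]:
                    for lb in label_sets[v]:
                        totals[(la, lb)] = totals.get((la, lb), 0.0) + w2
                extend(path + [v], w2)

    for start in range(n):
        extend([start], 1.0)
    return totals


def test_feature_matrix_matches_dag_path_enumeration():
    W = np.array([
        [0.0, 0.9, 0.3, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.5, 0.0],
        [0.0, 0.0, 0.0, 0.9, 0.2],
        [0.0, 0.0, 0.0, 0.0, 0.7],
        [0.0, 0.0, 0.0, 0.0, 0.0],
    ])
    label_sets = [{"a"}, {"b"}, {"b", "c"}, {"d"}, {"a", "e"}]
    from cpirex.apg_kernel import LabelAllocation

    labels = sorted({l for s in label_sets for l in s})
    L = np.zeros((5, len(labels)))
    for i, s in enumerate(label_sets):
        for lab in s:
            L[i, labels.index(lab)] = 1.0
    M, truncated = all_paths_matrix(W)
    assert not truncated
    G = feature_matrix(LabelAllocation(L=L, labels=labels), M).G
    expected = _bruteforce_dag_feature_matrix(W, label_sets)
    for (la, lb), val in expected.items():
        assert G[labels.index(la), labels.index(lb)] == pytest.approx(val, abs=1e-9)
    assert G.sum() == pytest.approx(sum(expected.values()), abs=1e-9)


class TestKernelMatrix:
    def test_single_instance_unit_diagonal(self):
        inst = chain_instance(["COMPOUND_C", "binds", "PROTEIN_C"], 0, 2)
        K, excluded = apg_kernel_matrix([inst], APGParams())
        assert excluded == []
        assert K[0, 0] == pytest.approx(1.0)

    def test_structurally_identical_instances_offdiagonal_one(self):
        a = chain_instance(["COMPOUND_C", "binds", "PROTEIN_C"], 0, 2, "pa")
        b = chain_instance(["COMPOUND_C", "binds", "PROTEIN_C"], 0, 2, "pb")
        K, _ = apg_kernel_matrix([a, b], APGParams())
        assert K[0, 1] == pytest.approx(1.0)

    def test_symmetric_psd_unit_diagonal_on_synthetic(self, synthetic_instances):
        K, excluded = apg_kernel_matrix(synthetic_instances, APGParams())
        assert excluded == []
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_degenerate_instances_are_excluded(self):
        good = chain_instance(["COMPOUND_C", "binds", "PROTEIN_C"], 0, 2, "good")
        bad = make_instance(
            "heparin cofactor II binds heparin .",
            [("heparin cofactor", "compound"), ("heparin cofactor II", "protein")],
        )
        K, excluded = apg_kernel_matrix([good, bad], APGParams())
        assert K.shape == (1, 1)
        assert excluded == [bad.pair.pair_id]


def test_raising_shortest_path_weight_is_monotone_on_chain():
    # weights kept inside the convergent regime (rho = w_sp * sqrt(2) < 1)
    values = []
    for w_sp in (0.35, 0.5, 0.65):
        inst = chain_instance(["COMPOUND_C", "binds", "PROTEIN_C"], 0, 2)
        params = APGParams(w_sp=w_sp, w_other=0.3)
        graph, alloc = build_weighted_graph(inst, params)
        M, _ = all_paths_matrix(graph.W)
        G = feature_matrix(alloc, M).G
        i = alloc.labels.index("COMPOUND_C")
        j = alloc.labels.index("PROTEIN_C")
        values.append(G[i, j])
    assert values == sorted(values)
    assert values[0] < values[-1]


def test_params_validate():
    with pytest.raises(ValueError):
        APGParams(w_sp=0.3, w_other=0.9)
    with pytest.raises(ValueError):
        APGParams(c=0.0)
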
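import numpy as np
import pandas as pd
import pytest

from perturbrank import features as ft
from perturbrank.features import (
    AlignmentError,
    DETFSet,
    FeatureMatrix,
    apply_normalization,
    base_features,
    cap_detfs,
    cluster_subsample,
    compute_detfs,
    drop_constant_features,
    minmax_normalize,
    polynomial_expand,
    propagate,
    summarize_propagation,
    topological_features,
)
from perturbrank.graphio import InteractionGraph, NormalizedAdjacency, PathwayCollection, normalize_adjacency
import scipy.sparse as sp


def zero_adjacency(n):
    return NormalizedAdjacency("forward", sp.csr_matrix((n, n)))


class TestComputeDetfs:
    def test_no_change_gives_empty_set(self):
        s = pd.Series({"A": 1.0, "B": 2.0})
        assert len(compute_detfs(s, s, {"A", "B"}, 1.0)) == 0

    def test_two_log2_units_up(self):
        init = pd.Series({"T": 1.0, "X": 1.0})
        fin = pd.Series({"T": 4.0, "X": 1.0})
        d = compute_detfs(init, fin, {"T"}, lfc_threshold=1.0)
        assert d.labels == {"T": 1}

    def test_downregulation_and_non_tf_ignored(self):
        init = pd.Series({"T": 4.0, "G": 4.0})
        fin = pd.Series({"T": 1.0, "G": 1.0})
        d = compute_detfs(init, fin, {"T"}, lfc_threshold=1.0)
        assert d.labels == {"T": -1}

    def test_min_expr_suppresses_low_expression(self):
        init = pd.Series({"T": 0.001})
        fin = pd.Series({"T": 0.01})
        assert len(compute_detfs(init, fin, {"T"}, 1.0, min_expr=0.5)) == 0

    def test_mismatched_universe_errors(self):
        with pytest.raises(AlignmentError):
            compute_detfs(pd.Series({"A": 1.0}), pd.Series({"B": 1.0}), {"A"})

    def test_planted_targets_recovered_at_zero_noise(self, small_world):
        # every TF target is directly perturbed, so it must appear in the
        # derived DETF set with the sign of its annotated effect
        for ds in small_world.train:
            drug = small_world.world.drug(ds.drug_id)
            for t, eff in drug.known_targets.items():
                if t in small_world.world.tf_universe:
                    assert ds.detfs.labels.get(t) == eff


class TestCapDetfs:
    def make(self, n):
        return DETFSet({f"T{i}": 1 for i in range(n)}, {f"T{i}" for i in range(n)})

    def test_under_cap_unchanged(self):
        d = cap_detfs(self.make(40), 100, seed=0)
        assert len(d) == 40 and d.capped

    def test_over_cap_deterministic(self):
        a = cap_detfs(self.make(250), 100, seed=11)
        b = cap_detfs(self.make(250), 100, seed=11)
        assert len(a) == 100 and a.labels == b.labels

    def test_different_seeds_differ(self):
        a = cap_detfs(self.make(250), 100, seed=1)
        b = cap_detfs(self.make(250), 100, seed=2)
        assert a.labels != b.labels

    def test_invalid_cap(self):
        with pytest.raises(ValueError):
            cap_detfs(self.make(5), 0, seed=0)


class TestPropagate:
    def test_zero_adjacency_pads_zeros(self):
        X = FeatureMatrix(["a", "b"], ["expr", "detf"], np.ones((2, 2)))
        Z = propagate(X, zero_adjacency(2), zero_adjacency(2), K=5)
        assert Z.shape == (2, 2 * 11)
        assert np.allclose(Z.values[:, 2:], 0)
        assert np.allclose(Z.values[:, :2], 1)

    def test_chain_hop1_indicator(self, chain_graph):
        # DETF indicator on A; forward hop-1 lands on B
        X = FeatureMatrix(["A", "B", "C"], ["expr", "detf"],
                          np.column_stack([np.zeros(3), [1.0, 0, 0]]))
        A_fwd = normalize_adjacency(chain_graph, "forward")
        A_rev = normalize_adjacency(chain_graph, "reverse")
        Z = propagate(X, A_fwd, A_rev, K=2)
        col = Z.col_names.index("rev1_detf")
        assert np.allclose(Z.values[:, col], [0, 1, 0])

    def test_k_zero_is_identity(self):
        X = FeatureMatrix(["a"], ["expr", "detf"], np.array([[2.0, -1.0]]))
        Z = propagate(X, zero_adjacency(1), zero_adjacency(1), K=0)
        assert np.array_equal(Z.values, X.values)

    def test_width_law_and_linearity(self, small_world, small_adjacencies):
        g = small_world.world.graph
        A_fwd, A_rev = small_adjacencies
        rng = np.random.default_rng(0)
        X = FeatureMatrix(list(g.node_ids), ["expr", "detf"],
                          rng.normal(size=(g.n_nodes, 2)))
        Z = propagate(X, A_fwd, A_rev, K=5)
        assert Z.shape[1] == 2 * (2 * 5 + 1)
        X3 = FeatureMatrix(list(g.node_ids), ["expr", "detf"], 3.0 * X.values)
        Z3 = propagate(X3, A_fwd, A_rev, K=5)
        assert np.allclose(Z3.values, 3.0 * Z.values)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        n = 12
        edges = [(int(a), int(b), "ppi", 1)
                 for a, b in rng.integers(0, n, size=(30, 2)) if a != b]
        ids = [f"N{i}" for i in range(n)]
        g = InteractionGraph(ids, edges)
        X = FeatureMatrix(ids, ["expr", "detf"], rng.normal(size=(n, 2)))
        Z = propagate(X, normalize_adjacency(g, "forward"),
                      normalize_adjacency(g, "reverse"), K=3)
        perm = rng.permutation(n)
        ids_p = [ids[i] for i in perm]
        g_p = InteractionGraph(
            ids_p, [(int(np.where(perm == s)[0][0]), int(np.where(perm == t)[0][0]), ty, sg)
                    for s, t, ty, sg in edges]
        )
        X_p = FeatureMatrix(ids_p, ["expr", "detf"], X.values[perm])
        Z_p = propagate(X_p, normalize_adjacency(g_p, "forward"),
                        normalize_adjacency(g_p, "reverse"), K=3)
        assert np.allclose(Z_p.values, Z.values[perm])

    def test_dimension_mismatch(self):
        X = FeatureMatrix(["a", "b"], ["expr", "detf"], np.ones((2, 2)))
        with pytest.raises(AlignmentError):
            propagate(X, zero_adjacency(3), zero_adjacency(3), K=1)


class TestSummarize:
    def propagated(self, vals, K=2):
        d = 1
        names = ["v"] + [f"{dr}{k}_v" for dr in ("fwd", "rev") for k in range(1, K + 1)]
        return FeatureMatrix(["r"], names, np.asarray(vals, dtype=float).reshape(1, -1),
                             stage="propagated")

    def test_constant_row_statistics(self):
        c, K = 3.5, 2
        Z = self.propagated([0.0] + [c] * (2 * K), K=K)
        S = summarize_propagation(Z)
        stats = dict(zip(S.col_names[-8:], S.values[0, -8:]))
        assert stats["v_sum"] == pytest.approx(c * 2 * K)
        assert stats["v_mean"] == pytest.approx(c)
        assert stats["v_std"] == 0.0
        assert stats["v_p25"] == stats["v_median"] == stats["v_p75"] == pytest.approx(c)

    def test_median_linear_interpolation(self):
        # ten propagated columns alternating 0/1 -> median exactly 0.5
        Z = self.propagated([9.9] + [0, 1] * 5, K=5)
        S = summarize_propagation(Z)
        assert S.values[0, S.col_names.index("v_median")] == pytest.approx(0.5)

    def test_order_statistics_sorted(self, small_world, small_adjacencies):
        g = small_world.world.graph
        rng = np.random.default_rng(1)
        X = FeatureMatrix(list(g.node_ids), ["expr", "detf"],
                          rng.normal(size=(g.n_nodes, 2)))
        S = summarize_propagation(propagate(X, *small_adjacencies, K=4))
        for base in ("expr", "detf"):
            cols = {s: S.col_names.index(f"{base}_{s}")
                    for s in ("min", "p25", "median", "p75", "max")}
            v = S.values
            assert np.all(v[:, cols["min"]] <= v[:, cols["p25"]] + 1e-12)
            assert np.all(v[:, cols["p25"]] <= v[:, cols["median"]] + 1e-12)
            assert np.all(v[:, cols["median"]] <= v[:, cols["p75"]] + 1e-12)
            assert np.all(v[:, cols["p75"]] <= v[:, cols["max"]] + 1e-12)


class TestTopological:
    def graph(self):
        # D -> A -> T (TF), B isolated sink
        return InteractionGraph(
            ["D", "A", "T", "B"],
            [(0, 1, "signaling", 1), (1, 2, "signaling", 1)],
        )

    def detfs(self, labels):
        return DETFSet(labels, set(labels))

    def empty_paths(self):
        return PathwayCollection({"P": {"ZZZ"}}, "x")

    def test_one_hop_upstream(self):
        T = topological_features(self.graph(), self.detfs({"T": 1}), self.empty_paths())
        a = T.row_ids.index("A")
        assert T.values[a, 1] == 1 and T.values[a, 2] == 100.0

    def test_unreachable_gets_sentinel(self):
        T = topological_features(self.graph(), self.detfs({"T": 1}), self.empty_paths())
        b = T.row_ids.index("B")
        assert T.values[b, 1] == 4  # sentinel = n_nodes
        assert T.values[b, 2] == 0.0

    def test_partial_reachability_percentage(self):
        g = InteractionGraph(
            ["P", "T1", "T2", "T3", "T4"],
            [(0, 1, "ppi", 1), (0, 2, "ppi", 1)],
        )
        d = self.detfs({"T1": 1, "T2": -1, "T3": 1, "T4": -1})
        T = topological_features(g, d, self.empty_paths())
        assert T.values[0, 2] == pytest.approx(50.0)

    def test_shared_pathway_counts(self):
        g = self.graph()
        paths = PathwayCollection({"p1": {"A", "T"}, "p2": {"A", "T", "D"}, "p3": {"B"}}, "x")
        T = topological_features(g, self.detfs({"T": 1}), paths)
        assert T.values[T.row_ids.index("A"), 0] == 2
        assert T.values[T.row_ids.index("B"), 0] == 0

    def test_empty_detf_set_all_zero(self):
        d = DETFSet({}, set())
        T = topological_features(self.graph(), d, self.empty_paths())
        assert np.allclose(T.values, 0)

    def test_min_path_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            edges = [(int(a), int(b), "ppi", 1)
                     for a, b in rng.integers(0, n, size=(3 * n, 2))]
            ids = [f"N{i}" for i in range(n)]
            g = InteractionGraph(ids, edges)
            detf_nodes = rng.choice(n, size=min(3, n), replace=False)
            d = DETFSet({ids[i]: 1 for i in detf_nodes}, {ids[i] for i in detf_nodes})
            T = topological_features(g, d, self.empty_paths())
            G = nx.DiGraph()
            G.add_nodes_from(range(n))
            G.add_edges_from([(s, t) for s, t, _, _ in g.edges])
            for p in range(n):
                best = min(
                    (nx.shortest_path_length(G, p, int(t))
                     for t in detf_nodes if nx.has_path(G, p, int(t))),
                    default=n,
                )
                assert T.values[p, 1] == best


class TestExpansionPruningScaling:
    def test_degree_two_basis(self):
        F = FeatureMatrix(["r"], ["a", "b"], np.array([[2.0, 3.0]]), stage="summarized")
        E = polynomial_expand(F)
        assert E.shape[1] == 6
        assert np.allclose(sorted(E.values[0]), sorted([1, 2, 3, 4, 6, 9]))

    def test_column_count_formula(self):
        d = 5
        F = FeatureMatrix(["r", "s"], [f"c{i}" for i in range(d)],
                          np.random.default_rng(0).normal(size=(2, d)), stage="summarized")
        E = polynomial_expand(F)
        assert E.shape[1] == 1 + 2 * d + d * (d - 1) // 2

    def test_drop_constant_rules(self):
        F = FeatureMatrix(
            ["a", "b", "c"], ["const", "tiny", "ok"],
            np.array([[5.0, 0.0, 1.0], [5.0, 1e-15, 2.0], [5.0, 0.0, 3.0]]),
        )
        out = drop_constant_features(F)
        assert out.col_names == ["ok"]

    def test_drop_constant_identity_and_all_constant_error(self):
        F = FeatureMatrix(["a", "b"], ["x", "y"], np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert drop_constant_features(F).col_names == ["x", "y"]
        C = FeatureMatrix(["a", "b"], ["x"], np.array([[1.0], [1.0]]))
        with pytest.raises(ValueError):
            drop_constant_features(C)

    def test_minmax_basic_and_idempotent(self):
        F = FeatureMatrix(["a", "b", "c"], ["x"], np.array([[1.0], [3.0], [5.0]]))
        N = minmax_normalize(F)
        assert np.allclose(N.values.ravel(), [0, 0.5, 1])
        again = minmax_normalize(N)
        assert np.allclose(again.values, N.values)

    def test_minmax_constant_column_rejected(self):
        C = FeatureMatrix(["a", "b"], ["x"], np.array([[1.0], [1.0]]))
        with pytest.raises(ZeroDivisionError, match="drop_constant"):
            minmax_normalize(C)

    def test_apply_normalization_clips_held_out_rows(self):
        F = FeatureMatrix(["a", "b"], ["x"], np.array([[0.0], [10.0]]))
        N = minmax_normalize(F)
        H = FeatureMatrix(["h1", "h2"], ["x"], np.array([[-5.0], [20.0]]))
        out = apply_normalization(H, N)
        assert np.allclose(out.values.ravel(), [0.0, 1.0])


class TestClusterSubsample:
    def normalized(self, vals):
        F = FeatureMatrix([f"r{i}" for i in range(len(vals))], ["x", "y"],
                          np.asarray(vals, dtype=float))
        return minmax_normalize(F)

    def test_k1_uniform_sample(self):
        rng = np.random.default_rng(0)
        F = self.normalized(rng.normal(size=(50, 2)))
        idx = cluster_subsample(F, k=1, per_cluster=10, seed=0)
        assert len(idx) == 10 and len(set(idx)) == 10

    def test_none_keeps_all_rows(self):
        F = self.normalized(np.random.default_rng(0).normal(size=(20, 2)))
        assert np.array_equal(cluster_subsample(F, k=5, per_cluster=None), np.arange(20))

    def test_two_blobs_balanced(self):
        rng = np.random.default_rng(3)
        blob_a = rng.normal(0, 0.05, size=(40, 2))
        blob_b = rng.normal(5, 0.05, size=(40, 2))
        F = self.normalized(np.vstack([blob_a, blob_b]))
        idx = cluster_subsample(F, k=2, per_cluster=10, seed=1)
        assert len(idx) == 20
        assert (idx < 40).sum() == 10 and (idx >= 40).sum() == 10

    def test_parameter_errors(self):
        F = self.normalized(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            cluster_subsample(F, k=2, per_cluster=0, seed=0)
        with pytest.raises(ValueError):
            cluster_subsample(F, k=50, per_cluster=1, seed=0)


def test_stage1_pipeline_is_pure(small_world, small_adjacencies):
    from perturbrank.features import build_feature_matrix

    w = small_world.world
    ds = small_world.train[0]
    A_fwd, A_rev = small_adjacencies
    a = build_feature_matrix(w.graph, ds.initial, ds.detfs, w.pathways, A_fwd, A_rev,
                             K=3, cap_seed=5)
    b = build_feature_matrix(w.graph, ds.initial, ds.detfs, w.pathways, A_fwd, A_rev,
                             K=3, cap_seed=5)
    assert a.col_names == b.col_names
    assert np.array_equal(a.values, b.values)
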
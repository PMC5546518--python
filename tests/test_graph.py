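"""Correlation matrices, cost thresholding, efficiencies, null references."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_residuals
from oracles import (
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    floyd_warshall,
    random_graph,
)
from scnet.graph import (
    BinaryGraph,
    GroupCorrelationMatrix,
    ThresholdError,
    correlation_matrix,
    edges_for_cost,
    efficiency_profile,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    random_reference,
    reference_efficiencies,
    regular_reference,
    shortest_paths,
    small_world_check,
    threshold_by_cost,
    watts_strogatz_like,
)


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adjacency=adj)


class TestCorrelationMatrix:
    def test_duplicated_region_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4))
        x[:, 1] = x[:, 0]
        resid = make_residuals(x, ["g"] * 10)
        corr = correlation_matrix(resid, "g")
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(corr.r) == 0)

    def test_independent_noise_correlations_vanish(self):
        rng = np.random.default_rng(1)
        resid = make_residuals(rng.standard_normal((5000, 12)), ["g"] * 5000)
        corr = correlation_matrix(resid, "g")
        assert np.abs(corr.r).max() < 0.1

    def test_zero_variance_region_zeroed_with_warning(self):
        x = np.random.default_rng(2).normal(size=(8, 4))
        x[:, 2] = 1.0
        resid = make_residuals(x, ["g"] * 8)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_matrix(resid, "g")
        assert np.all(corr.r[2] == 0) and np.all(corr.r[:, 2] == 0)

    def test_too_few_subjects_rejected(self):
        resid = make_residuals(np.random.default_rng(3).normal(size=(3, 4)), ["g"] * 3)
        with pytest.raises(ValueError, match="fewer than 4"):
            correlation_matrix(resid, "g")


class TestThresholdByCost:
    def test_cost_one_gives_complete_graph(self):
        rng = np.random.default_rng(4)
        r = np.corrcoef(rng.normal(size=(20, 6)), rowvar=False)
        np.fill_diagonal(r, 0)
        g = threshold_by_cost(
            GroupCorrelationMatrix(r=r, n_subjects=20, group="g"), 1.0
        )
        assert g.K == 15 and g.cost == 1.0

    def test_edge_count_at_study_comparison_cost(self):
        # N=68: K = round(0.095 * 2278) = 216
        assert edges_for_cost(68, 0.095) == 216
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 68))
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, 0)
        g = threshold_by_cost(
            GroupCorrelationMatrix(r=r, n_subjects=40, group="g"), 0.095
        )
        assert g.K == 216

    def test_exhaustive_ranking_on_four_nodes(self):
        r = np.zeros((4, 4))
        pairs = {(0, 1): 0.9, (2, 3): -0.8, (0, 2): 0.7, (0, 3): 0.1, (1, 2): 0.05}
        for (i, j), v in pairs.items():
            r[i, j] = r[j, i] = v
        g = threshold_by_cost(
            GroupCorrelationMatrix(r=r, n_subjects=10, group="g"), 0.5
        )
        assert g.K == 3
        assert set(g.edges()) == {(0, 1), (2, 3), (0, 2)}

    def test_tiny_cost_rejected(self):
        r = np.eye(4) * 0
        corr = GroupCorrelationMatrix(r=r, n_subjects=10, group="g")
        with pytest.raises(ThresholdError):
            threshold_by_cost(corr, 0.01)

    def test_nested_thresholds_and_monotone_global_efficiency(self):
        rng = np.random.default_rng(6)
        r = np.corrcoef(rng.normal(size=(30, 15)), rowvar=False)
        np.fill_diagonal(r, 0)
        corr = GroupCorrelationMatrix(r=r, n_subjects=30, group="g")
        prev_edges, prev_eff = set(), 0.0
        for cost in (0.1, 0.2, 0.35, 0.6, 1.0):
            g = threshold_by_cost(corr, cost)
            edges = set(g.edges())
            assert prev_edges <= edges
            eff = global_efficiency(g)
            assert eff >= prev_eff - 1e-15
            prev_edges, prev_eff = edges, eff


class TestShortestPaths:
    def test_chain_and_disconnection(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        d = shortest_paths(g)
        assert d[0, 2] == 2
        g2 = graph_from_edges(4, [(0, 1), (2, 3)])
        d2 = shortest_paths(g2)
        assert np.isinf(d2[0, 2]) and np.isinf(d2[1, 3])

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            adj = random_graph(rng, n_max=20)
            g = BinaryGraph(adjacency=adj)
            np.testing.assert_array_equal(shortest_paths(g), floyd_warshall(adj))


class TestEfficiencies:
    def test_closed_forms(self):
        k4 = graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert global_efficiency(k4) == pytest.approx(1.0)
        assert local_efficiency(graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])) == 1.0
        assert nodal_efficiency(k4, 0) == pytest.approx(1.0)

        empty = graph_from_edges(5, [])
        assert global_efficiency(empty) == 0.0
        assert nodal_efficiency(empty, 0) == 0.0

        p3 = graph_from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(p3) == pytest.approx(5 / 6)
        assert nodal_efficiency(p3, 1) == pytest.approx(1.0)
        assert nodal_efficiency(p3, 0) == pytest.approx(0.75)

        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert local_efficiency(star) == 0.0

        k4_minus = graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        assert local_efficiency(k4_minus) == pytest.approx(11 / 12)

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            adj = random_graph(rng)
            g = BinaryGraph(adjacency=adj)
            assert global_efficiency(g) == pytest.approx(
                brute_global_efficiency(adj), abs=1e-12
            )
            assert local_efficiency(g) == pytest.approx(
                brute_local_efficiency(adj), abs=1e-12
            )
            np.testing.assert_allclose(
                nodal_efficiency(g), brute_nodal_efficiency(adj), atol=1e-12
            )

    def test_networkx_cross_check(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            adj = random_graph(rng)
            g = BinaryGraph(adjacency=adj)
            gx = nx.from_numpy_array(adj)
            assert global_efficiency(g) == pytest.approx(
                nx.global_efficiency(gx), abs=1e-12
            )
            assert local_efficiency(g) == pytest.approx(
                nx.local_efficiency(gx), abs=1e-12
            )

    def test_global_equals_mean_nodal(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            g = BinaryGraph(adjacency=random_graph(rng))
            assert global_efficiency(g) == pytest.approx(
                float(np.mean(nodal_efficiency(g))), abs=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_adding_an_edge_never_decreases_global_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_graph(rng)
        n = adj.shape[0]
        missing = [
            (i, j) for i in range(n) for j in range(i + 1, n) if not adj[i, j]
        ]
        if not missing:
            return
        i, j = missing[int(rng.integers(len(missing)))]
        before = global_efficiency(BinaryGraph(adjacency=adj))
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        after = global_efficiency(BinaryGraph(adjacency=adj2))
        assert after >= before - 1e-15


class TestReferences:
    def test_ring_of_six(self):
        g = regular_reference(6, 6)
        assert g.K == 6
        assert np.all(g.adjacency.sum(axis=0) == 2)

    def test_partial_second_shell_in_node_order(self):
        g = regular_reference(5, 7)
        assert g.K == 7
        ring = {(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)}
        assert ring <= set(g.edges())
        assert set(g.edges()) - ring == {(0, 2), (1, 3)}

    @pytest.mark.parametrize("n,k", [(10, 13), (68, 216), (7, 21)])
    def test_exact_edge_count_contract(self, n, k):
        assert regular_reference(n, k).K == k
        for g in random_reference(n, k, seed=1, realizations=3):
            assert g.K == k and g.N == n

    def test_random_reference_saturation(self):
        (g,) = random_reference(6, 15, seed=2, realizations=1)
        assert global_efficiency(g) == 1.0

    def test_random_reference_matches_independent_sampler(self):
        # oracle: networkx gnm_random_graph, an independent G(N,K) sampler
        ours = [
            global_efficiency(g)
            for g in random_reference(68, 216, seed=3, realizations=100)
        ]
        theirs = [
            nx.global_efficiency(nx.gnm_random_graph(68, 216, seed=s))
            for s in range(100)
        ]
        se = np.sqrt(np.var(ours) / 100 + np.var(theirs) / 100)
        assert abs(np.mean(ours) - np.mean(theirs)) < 3 * se

    def test_reproducible_given_seed(self):
        a = random_reference(20, 40, seed=5, realizations=2)
        b = random_reference(20, 40, seed=5, realizations=2)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.adjacency, gb.adjacency)


class TestSmallWorld:
    def test_lattice_fails_global_inequality(self):
        n, k = 68, 216
        lattice = regular_reference(n, k)
        refs = reference_efficiencies(n, k, seed=0)
        verdict = small_world_check(
            global_efficiency(lattice), local_efficiency(lattice), **refs
        )
        assert not verdict.is_small_world
        assert verdict.margins["eglob_above_reg"] <= 0

    def test_random_graph_fails_local_inequality_in_expectation(self):
        n, k = 68, 216
        margins = []
        for seed in range(25):
            (g,) = random_reference(n, k, seed=1000 + seed, realizations=1)
            refs = reference_efficiencies(n, k, seed=seed)
            v = small_world_check(
                global_efficiency(g), local_efficiency(g), **refs
            )
            margins.append(v.margins["eloc_above_rand"])
        ws_margins = []
        for seed in range(10):
            g = watts_strogatz_like(n, k, 0.1, seed=seed)
            refs = reference_efficiencies(n, k, seed=seed)
            v = small_world_check(
                global_efficiency(g), local_efficiency(g), **refs
            )
            ws_margins.append(v.margins["eloc_above_rand"])
        assert abs(np.mean(margins)) < 0.5 * np.mean(ws_margins)

    def test_profile_verdict_on_small_world_covariance(self):
        # a covariance network sampled from a small-world ground truth
        rng = np.random.default_rng(11)
        g = watts_strogatz_like(30, 90, 0.1, seed=3)
        corr = np.eye(30) + 0.3 * g.adjacency
        vals, vecs = np.linalg.eigh(corr)
        corr = (vecs * np.clip(vals, 1e-6, None)) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        x = rng.multivariate_normal(np.zeros(30), corr, size=4000, method="eigh")
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, 0)
        profile = efficiency_profile(
            GroupCorrelationMatrix(r=r, n_subjects=4000, group="g"),
            cost_grid=[0.2],
            seed=4,
        )
        assert profile.small_world_at(0.2).is_small_world

    def test_profile_requires_cost_on_grid(self):
        rng = np.random.default_rng(12)
        r = np.corrcoef(rng.normal(size=(30, 10)), rowvar=False)
        np.fill_diagonal(r, 0)
        profile = efficiency_profile(
            GroupCorrelationMatrix(r=r, n_subjects=30, group="g"),
            cost_grid=[0.3],
            seed=0,
        )
        with pytest.raises(ValueError, match="grid"):
            profile.small_world_at(0.11)

    def test_watts_strogatz_like_edge_count_and_limits(self):
        g0 = watts_strogatz_like(20, 40, 0.0, seed=0)
        assert np.array_equal(g0.adjacency, regular_reference(20, 40).adjacency)
        g1 = watts_strogatz_like(20, 40, 0.5, seed=1)
        assert g1.K == 40
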
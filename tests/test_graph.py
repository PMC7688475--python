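"""Elastic principal tree: energy analytics, fitting, grammar, projection."""

import numpy as np
import pytest

from medtraj.graph import (
    ElasticParams,
    PrincipalGraph,
    explained_variance,
    extend_leaves,
    fit_node_positions,
    graph_energy,
    grow_tree,
    partition_points,
    project_point,
    project_points,
    prune_tree,
)


PARAMS = ElasticParams(lam=0.05, mu=0.1, alpha=0.01)


class TestEnergy:
    def test_msd_zero_when_points_on_nodes(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0]])
        G = PrincipalGraph(nodes, [(0, 1)], PARAMS)
        X = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        assert graph_energy(G, X).MSD == pytest.approx(0.0)

    def test_harmonic_star_has_zero_bending_energy(self):
        # center at the mean of its three leaves
        leaves = np.array([[1.0, 0.0], [-0.5, 0.8], [-0.5, -0.8]])
        nodes = np.vstack([leaves.mean(axis=0), leaves])
        G = PrincipalGraph(nodes, [(0, 1), (0, 2), (0, 3)], PARAMS)
        assert graph_energy(G, nodes).U_R == pytest.approx(0.0, abs=1e-12)

    def test_single_edge_stretching_energy_is_lambda_d_squared(self):
        d = 3.0
        G = PrincipalGraph(np.array([[0.0, 0.0], [d, 0.0]]), [(0, 1)], PARAMS)
        e = graph_energy(G, np.zeros((1, 2)))
        # degrees <= 2 so the complexity penalty vanishes
        assert e.U_E == pytest.approx(PARAMS.lam * d**2)

    def test_branching_inflates_edge_penalty(self):
        # 3-star: every edge touches a degree-3 node -> lam + alpha per edge
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        G = PrincipalGraph(nodes, [(0, 1), (0, 2), (0, 3)], PARAMS)
        e = graph_energy(G, np.zeros((1, 2)))
        assert e.U_E == pytest.approx((PARAMS.lam + PARAMS.alpha) * 3.0)

    def test_trimming_caps_point_contribution(self):
        G = PrincipalGraph(np.zeros((1, 2)), [], ElasticParams(lam=0.1, r0=1.0))
        X = np.array([[10.0, 0.0], [0.5, 0.0]])
        assert graph_energy(G, X).MSD == pytest.approx((1.0 + 0.25) / 2)


class TestPartition:
    def test_point_on_node(self):
        nodes = np.array([[0.0], [1.0], [2.0], [3.0]])
        G = PrincipalGraph(nodes, [(0, 1), (1, 2), (2, 3)], PARAMS)
        labels, _, _ = partition_points(np.array([[2.0]]), G)
        assert labels[0] == 2

    def test_tie_goes_to_lowest_index(self):
        nodes = np.array([[0.0], [1.0]])
        G = PrincipalGraph(nodes, [(0, 1)], PARAMS)
        labels, _, _ = partition_points(np.array([[0.5]]), G)
        assert labels[0] == 0

    def test_matches_bruteforce_search(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        nodes = rng.normal(size=(5, 3))
        G = PrincipalGraph(nodes, [(i, i + 1) for i in range(4)], PARAMS)
        labels, _, _ = partition_points(X, G)
        brute = np.array([
            min(range(5), key=lambda j: float(np.sum((x - nodes[j]) ** 2))) for x in X
        ])
        assert (labels == brute).all()


class TestFitNodePositions:
    def test_symmetric_line_data_gives_symmetric_nodes(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(-1, 1, 400)
        X = np.column_stack([t, np.zeros_like(t)])
        G = PrincipalGraph(np.array([[-0.4, 0.1], [0.4, -0.1]]), [(0, 1)], PARAMS)
        fit, _ = fit_node_positions(G, X, tol=1e-10, max_iter=500)
        assert np.allclose(fit.nodes[0], -fit.nodes[1], atol=0.05)

    def test_energy_non_increasing(self, star3):
        X, _ = star3
        G = PrincipalGraph(X[[0, 50, 120]], [(0, 1), (1, 2)], PARAMS)
        _, trace = fit_node_positions(G, X)
        us = [e.U for e in trace]
        assert all(b <= a + 1e-9 for a, b in zip(us, us[1:]))

    def test_single_node_converges_to_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3)) + [1.0, -2.0, 0.5]
        G = PrincipalGraph(np.zeros((1, 3)), [], PARAMS)
        fit, _ = fit_node_positions(G, X, tol=1e-12, max_iter=50)
        assert np.allclose(fit.nodes[0], X.mean(axis=0), atol=1e-8)


class TestGrowTree:
    def test_line_data_yields_path(self, line_data):
        G, _ = grow_tree(line_data, n_nodes=10, seed=0)
        assert G.is_tree()
        assert len(G.leaves) == 2 and not G.branching_nodes

    def test_star_topology_recovered(self, star3):
        X, _ = star3
        G, _ = grow_tree(X, n_nodes=20, seed=0)
        G = prune_tree(G)
        assert len(G.leaves) == 3
        assert len(G.branching_nodes) == 1 and G.degrees[G.branching_nodes[0]] == 3

    def test_accepted_candidates_are_stepwise_minimal(self, line_data):
        G, report = grow_tree(line_data, n_nodes=6, seed=0)
        us = [e.U for e in report.energy_trace]
        for step, cand_energies in enumerate(report.step_candidate_energies):
            assert us[step + 1] <= cand_energies.min() + 1e-6

    def test_energy_non_increasing_across_steps(self, star3):
        X, _ = star3
        _, report = grow_tree(X, n_nodes=15, seed=3)
        us = [e.U for e in report.energy_trace]
        assert all(b <= a + 1e-9 for a, b in zip(us, us[1:]))

    def test_too_few_nodes_rejected(self, line_data):
        with pytest.raises(ValueError):
            grow_tree(line_data, n_nodes=1)

    def test_alpha_controls_branching_monotonically(self, star3):
        X, _ = star3
        n_branchings = []
        for alpha in (0.0, 0.01, 1.0):
            G, _ = grow_tree(X, n_nodes=18, seed=7,
                             params=ElasticParams(lam=0.05, mu=0.1, alpha=alpha))
            n_branchings.append(int((G.degrees >= 3).sum()))
        assert n_branchings[0] >= n_branchings[1] >= n_branchings[2]


class TestPrune:
    def test_path_unchanged(self):
        nodes = np.arange(4, dtype=float).reshape(-1, 1)
        G = PrincipalGraph(nodes, [(0, 1), (1, 2), (2, 3)], PARAMS)
        assert prune_tree(G).n_nodes == 4

    def test_single_edge_arm_removed(self):
        # Y tree: arms of lengths 1, 2, 2 edges
        nodes = np.zeros((6, 2))
        edges = [(0, 1), (0, 2), (2, 3), (0, 4), (4, 5)]
        G = PrincipalGraph(nodes, edges, PARAMS)
        out = prune_tree(G)
        assert out.n_nodes == 5 and len(out.leaves) == 2

    def test_pure_star_collapses_to_center_path_with_warning(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        G = PrincipalGraph(nodes, [(0, 1), (0, 2), (0, 3)], PARAMS)
        with pytest.warns(UserWarning, match="branching"):
            out = prune_tree(G)
        assert out.n_nodes == 3 and len(out.leaves) == 2


class TestExtendLeaves:
    def test_interior_projections_leave_graph_unchanged(self):
        G = PrincipalGraph(np.array([[0.0], [1.0]]), [(0, 1)], PARAMS)
        X = np.array([[0.2], [0.4], [0.6]])
        out = extend_leaves(G, X)
        assert np.allclose(out.nodes, G.nodes)

    def test_leaf_moves_to_farthest_ray_projection(self):
        G = PrincipalGraph(np.array([[0.0, 0.0], [1.0, 0.0]]), [(0, 1)], PARAMS)
        X = np.array([[1.5, 0.3], [0.1, 0.0]])
        out = extend_leaves(G, X)
        assert out.nodes[1, 0] == pytest.approx(1.5)

    def test_no_point_projects_onto_leaf_after_extension(self, line_data):
        G, _ = grow_tree(line_data, n_nodes=8, seed=0)
        out = extend_leaves(G, line_data)
        projs = project_points(line_data, out)
        leaf_hits = 0
        for p in projs:
            a, b = out.edges[p.edge]
            deg = out.degrees
            if (p.eps == 0.0 and deg[a] == 1) or (p.eps == 1.0 and deg[b] == 1):
                leaf_hits += 1
        assert leaf_hits == 0


class TestProjection:
    def test_midpoint_of_isolated_edge(self):
        G = PrincipalGraph(np.array([[0.0, 0.0], [2.0, 0.0]]), [(0, 1)], PARAMS)
        p = project_point(np.array([1.0, 1.0]), G)
        assert p.eps == pytest.approx(0.5) and p.sq_residual == pytest.approx(1.0)

    def test_point_on_node_has_zero_residual(self):
        G = PrincipalGraph(np.array([[0.0], [1.0], [2.0]]), [(0, 1), (1, 2)], PARAMS)
        p = project_point(np.array([0.0]), G)
        assert p.sq_residual == pytest.approx(0.0) and p.eps in (0.0, 1.0)

    def test_matches_per_edge_closed_form_oracle(self):
        rng = np.random.default_rng(4)
        nodes = rng.normal(size=(11, 3))
        edges = [(i, i + 1) for i in range(10)]
        G = PrincipalGraph(nodes, edges, PARAMS)
        X = rng.normal(size=(50, 3))
        for x, p in zip(X, project_points(X, G)):
            best = np.inf
            for a, b in edges:
                d = nodes[b] - nodes[a]
                t = np.clip((x - nodes[a]) @ d / (d @ d), 0, 1)
                best = min(best, float(np.sum((x - nodes[a] - t * d) ** 2)))
            assert p.sq_residual == pytest.approx(best, abs=1e-10)


class TestExplainedVariance:
    def test_points_on_graph_fully_explained(self):
        G = PrincipalGraph(np.array([[0.0, 0.0], [1.0, 0.0]]), [(0, 1)], PARAMS)
        X = np.array([[0.25, 0.0], [0.75, 0.0]])
        assert explained_variance(G, X) == pytest.approx(1.0)

    def test_low_noise_line_mostly_explained(self, line_data):
        G, _ = grow_tree(line_data, n_nodes=10, seed=0)
        G = extend_leaves(G, line_data)
        # noise sigma = 0.05 on arm length 4 -> residual variance ~ sigma^2 per
        # orthogonal direction, a tiny fraction of the total variance
        assert explained_variance(G, line_data) > 0.99

    def test_zero_variance_rejected(self):
        G = PrincipalGraph(np.zeros((2, 2)), [(0, 1)], PARAMS)
        with pytest.raises(ValueError):
            explained_variance(G, np.zeros((5, 2)))


def test_graph_json_roundtrip(tmp_path, star3):
    X, _ = star3
    G, _ = grow_tree(X, n_nodes=8, seed=0)
    path = tmp_path / "g.json"
    G.to_json(path)
    back = PrincipalGraph.from_json(path)
    assert np.allclose(back.nodes, G.nodes)
    assert back.edges == G.edges
    assert back.params == G.params
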
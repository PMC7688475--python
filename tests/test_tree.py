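"""Segment decomposition, data partitioning, root choice, pseudo-time."""

import itertools

import networkx as nx
import numpy as np
import pytest

from medtraj.graph import ElasticParams, PrincipalGraph, grow_tree, prune_tree
from medtraj.tree import (
    compute_pseudotime,
    decompose_segments,
    extract_trajectories,
    node_hop_distances,
    partition_by_segments,
    select_root,
)

PARAMS = ElasticParams()


def _graph(n, edges, dim=2, nodes=None):
    if nodes is None:
        rng = np.random.default_rng(0)
        nodes = rng.normal(size=(n, dim))
    return PrincipalGraph(np.asarray(nodes, float), edges, PARAMS)


def _oracle_segments(n, edges):
    """Union-find edge partition: edges sharing a degree-<=2 node join."""
    deg = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    parent = {e: e for e in edges}

    def find(e):
        while parent[e] != e:
            parent[e] = parent[parent[e]]
            e = parent[e]
        return e

    def union(e, f):
        parent[find(e)] = find(f)

    for e, f in itertools.combinations(edges, 2):
        shared = set(e) & set(f)
        if shared and deg[shared.pop()] <= 2:
            union(e, f)
    groups = {}
    for e in edges:
        groups.setdefault(find(e), set()).add(tuple(sorted(e)))
    return {frozenset(g) for g in groups.values()}


class TestDecomposeSegments:
    def test_path_is_one_segment(self):
        segs = decompose_segments(_graph(3, [(0, 1), (1, 2)]))
        assert len(segs) == 1 and segs[0].kind == "terminal"

    def test_y_graph_three_terminal_segments(self):
        segs = decompose_segments(_graph(4, [(0, 1), (0, 2), (0, 3)]))
        assert len(segs) == 3
        assert all(s.kind == "terminal" for s in segs)

    def test_cycle_plus_isolated_node(self):
        segs = decompose_segments(_graph(4, [(0, 1), (1, 2), (0, 2)]))
        kinds = sorted(s.kind for s in segs)
        assert kinds == ["cycle", "isolated"]
        cyc = next(s for s in segs if s.kind == "cycle")
        assert set(cyc.edges) == {(0, 1), (1, 2), (0, 2)}

    def test_edge_partition_property(self, star3):
        X, _ = star3
        G, _ = grow_tree(X, n_nodes=20, seed=0)
        segs = decompose_segments(G)
        covered = [e for s in segs for e in s.edges]
        assert sorted(covered) == sorted(G.edges)  # each edge exactly once

    def test_matches_exhaustive_oracle_on_all_small_connected_graphs(self):
        """Exhaustive check against a union-find oracle over every connected
        graph with up to 6 nodes (graph atlas)."""
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for g in graph_atlas_g():
            n = g.number_of_nodes()
            if n == 0 or n > 6 or g.number_of_edges() == 0:
                continue
            if not nx.is_connected(g):
                continue
            edges = [tuple(sorted(e)) for e in g.edges()]
            segs = decompose_segments(_graph(n, edges))
            got = {frozenset(s.edges) for s in segs if s.edges}
            assert got == _oracle_segments(n, edges), f"atlas graph with edges {edges}"
            checked += 1
        assert checked > 100


class TestPartitionBySegments:
    def test_degree_two_node_maps_to_unique_segment(self):
        nodes = [[0.0, 0], [1, 0], [2, 0]]
        G = _graph(3, [(0, 1), (1, 2)], nodes=nodes)
        segs = decompose_segments(G)
        labels = partition_by_segments(np.array([[1.0, 0.2]]), G, segs)
        assert labels[0] == segs[0].id

    def test_branching_node_uses_second_nearest(self):
        # Y: center at origin, arms along +x, +y, -x
        nodes = [[0.0, 0], [1, 0], [0, 1], [-1, 0]]
        G = _graph(4, [(0, 1), (0, 2), (0, 3)], nodes=nodes)
        segs = decompose_segments(G)
        by_leaf = {s.node_path[-1] if s.node_path[0] == 0 else s.node_path[0]: s.id for s in segs}
        # nearest node is the center; second nearest is node 2 (arm +y)
        labels = partition_by_segments(np.array([[0.05, 0.4]]), G, segs)
        assert labels[0] == by_leaf[2]

    def test_agrees_with_nearest_edge_rule_on_dense_tree(self, star3):
        X, _ = star3
        G, _ = grow_tree(X, n_nodes=30, seed=0)
        segs = decompose_segments(G)
        labels = partition_by_segments(X, G, segs)
        # independent rule: nearest edge -> its segment
        from medtraj.graph import project_points

        edge_to_seg = {}
        for s in segs:
            for e in s.edges:
                edge_to_seg[e] = s.id
        by_edge = np.array([
            edge_to_seg[tuple(sorted(G.edges[p.edge]))] for p in project_points(X, G)
        ])
        assert np.mean(labels == by_edge) >= 0.95


class TestSelectRoot:
    def test_concentrated_class_pins_the_node(self):
        nodes = np.array([[0.0], [5.0], [10.0]])
        G = _graph(3, [(0, 1), (1, 2)], nodes=nodes)
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(5, 0.1, 40),
                            rng.normal(10, 0.1, 40)]).reshape(-1, 1)
        labels = np.array(["target"] * 40 + ["other"] * 80)
        sel = select_root(G, X, labels, "target")
        assert sel.significant and sel.node == 0

    def test_uniform_distribution_flags_no_root(self):
        nodes = np.array([[0.0], [5.0]])
        G = _graph(2, [(0, 1)], nodes=nodes)
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(5, 0.1, 50)]).reshape(-1, 1)
        labels = np.tile(["a", "b"], 50)  # independent of position
        sel = select_root(G, X, labels, "a")
        assert not sel.significant and sel.node is None

    def test_absent_class_rejected(self):
        G = _graph(2, [(0, 1)], nodes=np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            select_root(G, np.zeros((3, 1)), np.array(["x", "x", "x"]), "missing")

    def test_planted_enrichment_recovered_on_fitted_tree(self, star3):
        X, truth = star3
        G, _ = grow_tree(X, n_nodes=20, seed=0)
        # plant the class at the node where arm 0's extreme points live
        from medtraj.graph import partition_points

        nearest, _, _ = partition_points(X, G)
        arm0_far = truth.index[(truth["branch"] == 0) & (truth["pseudotime"] > 0.8)]
        planted = np.bincount(nearest[arm0_far], minlength=G.n_nodes).argmax()
        labels = np.where(nearest == planted, "sick", "well")
        sel = select_root(G, X, labels, "sick")
        assert sel.significant and sel.node == planted


class TestTrajectories:
    def test_middle_root_of_path_gives_two(self):
        G = _graph(3, [(0, 1), (1, 2)])
        trajs = extract_trajectories(G, root=1)
        assert len(trajs) == 2
        assert {t.node_path for t in trajs} == {(1, 0), (1, 2)}

    def test_leaf_root_of_y_gives_two(self):
        G = _graph(4, [(0, 1), (0, 2), (0, 3)])
        trajs = extract_trajectories(G, root=1)
        assert len(trajs) == 2
        assert all(t.node_path[0] == 1 for t in trajs)

    def test_one_per_leaf(self, star3):
        X, _ = star3
        G, _ = grow_tree(X, n_nodes=25, seed=0)
        G = prune_tree(G)
        root = G.branching_nodes[0]
        trajs = extract_trajectories(G, root)
        assert len(trajs) == len(G.leaves)

    def test_invalid_root_rejected(self):
        G = _graph(3, [(0, 1), (1, 2)])
        with pytest.raises(ValueError):
            extract_trajectories(G, root=99)


class TestPseudotime:
    def _path_graph(self):
        nodes = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        return _graph(4, [(0, 1), (1, 2), (2, 3)], nodes=nodes)

    def test_root_incident_edge(self):
        G = self._path_graph()
        pt = compute_pseudotime(np.array([[0.3, 0.0]]), G, root=0)
        assert pt.table["pt"].iloc[0] == pytest.approx(0.3)

    def test_forward_branch_adds_eps(self):
        G = self._path_graph()
        # projection on edge (2,3) at eps=0.25; d0=2 < d1=3 -> Pt = 2.25
        pt = compute_pseudotime(np.array([[2.25, 0.0]]), G, root=0)
        assert pt.table["pt"].iloc[0] == pytest.approx(2.25)

    def test_backward_orientation_subtracts_eps(self):
        G = self._path_graph()
        # root at node 3: point at x=2.6 projects on edge (2,3) at eps=0.6
        # d0 = |3->2| = 1 > d1 = 0 -> Pt = 1 - 0.6 = 0.4
        pt = compute_pseudotime(np.array([[2.6, 0.0]]), G, root=3)
        assert pt.table["pt"].iloc[0] == pytest.approx(0.4)

    def test_hop_distances(self):
        G = self._path_graph()
        assert node_hop_distances(G, 0).tolist() == [0, 1, 2, 3]

    def test_pseudotime_continuous_along_trajectory(self, star3):
        X, _ = star3
        G, _ = grow_tree(X, n_nodes=25, seed=0)
        G = prune_tree(G)
        root = G.leaves[0]
        pt = compute_pseudotime(X, G, root)
        for tr in pt.trajectories:
            sub = pt.on_trajectory(tr.id).sort_values("pt")
            gaps = np.diff(sub["pt"].to_numpy())
            assert (gaps < 1.0).all()  # adjacent projections differ < 1 edge unit

    def test_spearman_against_arclength_truth(self, star3):
        from scipy.stats import spearmanr

        X, truth = star3
        G, _ = grow_tree(X, n_nodes=25, seed=0)
        G = prune_tree(G)
        root = int(np.argmin(np.linalg.norm(G.nodes, axis=1)))  # embedded root at origin
        pt = compute_pseudotime(X, G, root)
        for b in truth["branch"].unique():
            m = (truth["branch"] == b).to_numpy()
            rho = spearmanr(pt.table["pt"].to_numpy()[m], truth["pseudotime"][m]).statistic
            assert rho >= 0.95
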
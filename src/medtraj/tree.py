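"""Tree anatomy: non-branching segments, root choice, trajectories, pseudo-time.

A fitted principal tree is decomposed into *non-branching segments*: maximal
paths whose interior nodes have degree 2.  Internal segments join two
branching nodes, terminal segments end at a leaf; isolated cycles and
isolated nodes are kept as their own segments for generality.  Segments act
as tree-shaped clusters: each observation is labeled with the segment of its
nearest node (with a second-nearest-node rule at branching nodes).

Choosing a root node orients the tree.  Every root-to-leaf node path becomes
a *trajectory* — an ordered sequence of disease states — and each observation
receives a pseudo-time: its geodesic distance from the root to its projection
on the tree, measured in edge units,

    Pt(x) = d(root, E(0)) + eps   if E(0) is nearer the root than E(1),
    Pt(x) = d(root, E(0)) - eps   otherwise,

where {E, eps} is the projection of x onto edge E at fraction eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .graph import PrincipalGraph, partition_points, project_points

__all__ = [
    "Segment",
    "Trajectory",
    "PseudotimeTable",
    "RootSelection",
    "decompose_segments",
    "partition_by_segments",
    "select_root",
    "extract_trajectories",
    "compute_pseudotime",
    "node_hop_distances",
]


@dataclass(frozen=True)
class Segment:
    """Maximal non-branching node path of a graph."""

    id: int
    node_path: tuple[int, ...]
    kind: str  # internal | terminal | cycle | isolated

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            tuple(sorted((a, b)))
            for a, b in zip(self.node_path[:-1], self.node_path[1:])
        )

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(self.node_path)


@dataclass(frozen=True)
class Trajectory:
    """Ordered root-to-leaf node path (a clinical scenario)."""

    id: int
    node_path: tuple[int, ...]
    segment_ids: tuple[int, ...] = ()

    @property
    def leaf(self) -> int:
        return self.node_path[-1]

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            tuple(sorted((a, b)))
            for a, b in zip(self.node_path[:-1], self.node_path[1:])
        )


@dataclass
class PseudotimeTable:
    """Per-observation projection, pseudo-time and trajectory membership."""

    table: pd.DataFrame  # columns: edge, eps, pt, segment, sq_residual
    trajectory_members: dict[int, np.ndarray]  # trajectory id -> bool mask
    root: int
    trajectories: list[Trajectory]

    def on_trajectory(self, trajectory_id: int) -> pd.DataFrame:
        return self.table[self.trajectory_members[trajectory_id]]


@dataclass(frozen=True)
class RootSelection:
    """Advisory root choice from class enrichment, with per-node statistics."""

    node: int | None
    significant: bool
    stats: pd.DataFrame  # per node: chi2, p, enriched


# ---------------------------------------------------------------------------
# segment decomposition


def decompose_segments(G: PrincipalGraph) -> list[Segment]:
    """Uniquely partition the edges into maximal non-branching segments.

    Depth-first walks start at branching (degree > 2) and terminal
    (degree < 2) nodes and follow degree-2 chains, storing visited *edges* so
    cycles are handled correctly: a connected component that is a pure cycle
    becomes a single cycle segment, and isolated nodes become singleton
    segments.
    """
    deg = G.degrees
    adj = G.adjacency()
    visited: set[tuple[int, int]] = set()
    segments: list[Segment] = []

    def walk(start: int, nxt: int) -> tuple[int, ...]:
        path = [start, nxt]
        visited.add(tuple(sorted((start, nxt))))
        while deg[path[-1]] == 2:
            prev, cur = path[-2], path[-1]
            nbs = [n for n in adj[cur] if n != prev]
            if not nbs:  # defensive: degree bookkeeping broken
                break
            nb = nbs[0]
            edge = tuple(sorted((cur, nb)))
            if edge in visited:
                break
            visited.add(edge)
            path.append(nb)
        return tuple(path)

    endpoints = [i for i in range(G.n_nodes) if deg[i] != 2 and deg[i] > 0]
    for start in endpoints:
        for nxt in adj[start]:
            if tuple(sorted((start, nxt))) in visited:
                continue
            path = walk(start, nxt)
            both_branch = deg[path[0]] > 2 and deg[path[-1]] > 2
            segments.append(
                Segment(len(segments), path, "internal" if both_branch else "terminal")
            )
    # remaining unvisited edges belong to pure cycles (all nodes degree 2);
    # the walk closes them, ending back at the start node
    for a, b in G.edges:
        if tuple(sorted((a, b))) in visited:
            continue
        segments.append(Segment(len(segments), walk(a, b), "cycle"))
    for i in range(G.n_nodes):
        if deg[i] == 0:
            segments.append(Segment(len(segments), (i,), "isolated"))
    return segments


def _node_to_segments(segments: list[Segment]) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for seg in segments:
        for node in seg.node_path:
            out.setdefault(node, [])
            if seg.id not in out[node]:
                out[node].append(seg.id)
    return out


def partition_by_segments(
    X: np.ndarray, G: PrincipalGraph, segments: list[Segment] | None = None
) -> np.ndarray:
    """Label each observation with the segment of its nearest node.

    If the nearest node is a branching node (shared by several segments), the
    chosen segment is the one containing the second-nearest node among all
    nodes of the candidate segments.
    """
    if segments is None:
        segments = decompose_segments(G)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    node_seg = _node_to_segments(segments)
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(G.nodes**2, axis=1)[None, :]
        - 2.0 * X @ G.nodes.T
    )
    nearest = np.argmin(d2, axis=1)
    labels = np.empty(len(X), dtype=int)
    for i, node in enumerate(nearest):
        cands = node_seg[int(node)]
        if len(cands) == 1:
            labels[i] = cands[0]
            continue
        best = (np.inf, -1)
        for sid in sorted(cands):
            others = [n for n in segments[sid].node_path if n != node]
            if not others:
                continue
            dmin = float(d2[i, others].min())
            if dmin < best[0]:
                best = (dmin, sid)
        labels[i] = best[1] if best[1] >= 0 else cands[0]
    return labels


# ---------------------------------------------------------------------------
# root selection


def select_root(
    G: PrincipalGraph,
    X: np.ndarray,
    class_labels: np.ndarray,
    target_class,
    p_threshold: float = 0.05,
) -> RootSelection:
    """Advise a root: the node most positively enriched in a target class.

    Each node defines a 2x2 contingency table (assigned to the node or not ×
    target class or not); the returned node maximizes the chi-square statistic
    among nodes whose observed in-node class count exceeds the expected one.
    If no node is both positively enriched and significant at ``p_threshold``
    the selection is flagged and the caller must supply a root explicitly.
    """
    class_labels = np.asarray(class_labels)
    is_target = class_labels == target_class
    if not is_target.any():
        raise ValueError(f"target class {target_class!r} absent from labels")
    nearest, _, _ = partition_points(np.asarray(X, float), G)
    rows = []
    n = len(class_labels)
    for node in range(G.n_nodes):
        member = nearest == node
        a = int(np.sum(member & is_target))
        b = int(np.sum(member & ~is_target))
        c = int(np.sum(~member & is_target))
        d = int(np.sum(~member & ~is_target))
        expected = (a + b) * (a + c) / n if n else 0.0
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            rows.append((node, 0.0, 1.0, False))
            continue
        chi2, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        rows.append((node, float(chi2), float(p), a > expected))
    stats = pd.DataFrame(rows, columns=["node", "chi2", "p", "enriched"]).set_index("node")
    eligible = stats[(stats["enriched"]) & (stats["p"] < p_threshold)]
    if eligible.empty:
        return RootSelection(node=None, significant=False, stats=stats)
    return RootSelection(node=int(eligible["chi2"].idxmax()), significant=True, stats=stats)


# ---------------------------------------------------------------------------
# trajectories and pseudo-time


def node_hop_distances(G: PrincipalGraph, root: int) -> np.ndarray:
    """Geodesic distance from the root to every node, in edge counts (BFS)."""
    if not 0 <= root < G.n_nodes:
        raise ValueError(f"root {root} not in graph")
    adj = G.adjacency()
    dist = np.full(G.n_nodes, -1, dtype=int)
    dist[root] = 0
    queue = [root]
    while queue:
        cur = queue.pop(0)
        for nb in adj[cur]:
            if dist[nb] < 0:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    return dist


def extract_trajectories(
    G: PrincipalGraph, root: int, segments: list[Segment] | None = None
) -> list[Trajectory]:
    """One root-to-leaf path per leaf of the tree (the root's own trivial
    zero-length path is excluded when the root is itself a leaf)."""
    if not 0 <= root < G.n_nodes:
        raise ValueError(f"root {root} not in graph")
    if not G.is_tree():
        raise ValueError("trajectories are defined for trees only")
    if segments is None:
        segments = decompose_segments(G)
    adj = G.adjacency()
    deg = G.degrees
    leaves = [i for i in range(G.n_nodes) if deg[i] <= 1 and i != root]
    # unique path root -> leaf by DFS with parent tracking
    parent = np.full(G.n_nodes, -1, dtype=int)
    order = [root]
    seen = {root}
    while order:
        cur = order.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                parent[nb] = cur
                order.append(nb)
    out = []
    for tid, leaf in enumerate(sorted(leaves)):
        path = [leaf]
        while path[-1] != root:
            path.append(int(parent[path[-1]]))
        path = tuple(reversed(path))
        edges = {tuple(sorted(e)) for e in zip(path[:-1], path[1:])}
        seg_ids = tuple(
            s.id for s in segments if any(e in edges for e in s.edges)
        )
        out.append(Trajectory(tid, path, seg_ids))
    return out


def compute_pseudotime(
    X: np.ndarray,
    G: PrincipalGraph,
    root: int,
    segments: list[Segment] | None = None,
    trajectories: list[Trajectory] | None = None,
    index=None,
) -> PseudotimeTable:
    """Pseudo-time of every observation plus its trajectory memberships.

    Each observation is projected onto the tree; with the projection on edge
    E at fraction eps and hop distances d0, d1 from the root to the edge's
    endpoints, Pt = d0 + eps if d0 < d1 else d0 - eps (edge units).  The
    observation belongs to every trajectory whose edge set contains E, and
    its pseudo-time is shared across those trajectories.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if segments is None:
        segments = decompose_segments(G)
    if trajectories is None:
        trajectories = extract_trajectories(G, root, segments)
    hop = node_hop_distances(G, root)
    projs = project_points(X, G)
    seg_labels = partition_by_segments(X, G, segments)
    pt = np.empty(len(X))
    edge_idx = np.empty(len(X), dtype=int)
    eps_arr = np.empty(len(X))
    resid = np.empty(len(X))
    for i, pr in enumerate(projs):
        a, b = G.edges[pr.edge]
        d0, d1 = hop[a], hop[b]
        pt[i] = d0 + pr.eps if d0 < d1 else d0 - pr.eps
        edge_idx[i] = pr.edge
        eps_arr[i] = pr.eps
        resid[i] = pr.sq_residual
    table = pd.DataFrame(
        {
            "edge": edge_idx,
            "eps": eps_arr,
            "pt": pt,
            "segment": seg_labels,
            "sq_residual": resid,
        },
        index=index if index is not None else pd.RangeIndex(len(X)),
    )
    members = {}
    for tr in trajectories:
        edge_keys = tr.edges
        members[tr.id] = np.array(
            [tuple(sorted(G.edges[e])) in edge_keys for e in edge_idx]
        )
    return PseudotimeTable(table=table, trajectory_members=members, root=root,
                           trajectories=list(trajectories))
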
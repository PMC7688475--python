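"""Elastic principal trees: energy, node optimization, grammar-based growth.

A principal tree is a set of nodes embedded in data space, joined by edges,
that approximates the data cloud while staying smooth and simple.  The fitted
embedding phi minimizes

    U = MSD + U_E + U_R

where MSD is the mean squared distance of each point to its nearest node
(optionally trimmed at radius R0), U_E penalizes edge stretching with an
elasticity modulus lambda (inflated by alpha at high-degree branchings), and
U_R penalizes stars whose center deviates from the mean of its neighbors
(bending modulus mu).  For a fixed topology and point-to-node partition the
problem is quadratic, so node positions are found exactly by solving a linear
system; alternating partition/solve steps ("splitting" algorithm) provably
decrease U.  The tree *structure* is searched by topological grammar: starting
from a two-node seed, every graph reachable by one application of "add a node
to a node" or "bisect an edge" is refitted and the lowest-energy candidate is
accepted, until the node budget is reached.  Post-processing prunes terminal
single-edge stubs and extends terminal edges so extreme points project onto
edge interiors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ElasticParams",
    "PrincipalGraph",
    "Projection",
    "EnergyBreakdown",
    "FitReport",
    "graph_energy",
    "partition_points",
    "fit_node_positions",
    "grow_tree",
    "prune_tree",
    "extend_leaves",
    "project_point",
    "project_points",
    "explained_variance",
]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic moduli of the graph embedding.

    lam : edge-stretching modulus (> 0), keeps edges short and equidistant.
    mu : star-bending modulus (>= 0), pulls star centers to neighbor means.
    alpha : branching-complexity penalty (>= 0), inflates lam at stars.
    r0 : trimming radius; points farther than r0 from every node do not
        contribute to the approximation term (default: infinite).
    """

    lam: float = 0.05
    mu: float = 0.1
    alpha: float = 0.01
    r0: float = np.inf

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.mu < 0 or self.alpha < 0:
            raise ValueError("mu and alpha must be >= 0")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


class EnergyBreakdown(NamedTuple):
    U: float
    MSD: float
    U_E: float
    U_R: float


class Projection(NamedTuple):
    """Nearest point of the piecewise-linear graph to a query vector.

    edge : index into the graph's edge list.
    eps : position along the edge as a fraction in [0, 1] (0 at the first
        endpoint, 1 at the second).
    point : the projected vector.
    sq_residual : squared distance from the query to the projection.
    """

    edge: int
    eps: float
    point: np.ndarray
    sq_residual: float


@dataclass
class PrincipalGraph:
    """Embedded undirected graph: node coordinates, edge list, elastic moduli."""

    nodes: np.ndarray  # (K, m)
    edges: list[tuple[int, int]]
    params: ElasticParams = field(default_factory=ElasticParams)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2:
            raise ValueError("nodes must be a (K, m) array")
        self.edges = [tuple(sorted((int(a), int(b)))) for a, b in self.edges]
        k = self.n_nodes
        for a, b in self.edges:
            if not (0 <= a < k and 0 <= b < k) or a == b:
                raise ValueError(f"invalid edge ({a}, {b}) for {k} nodes")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return [sorted(nb) for nb in adj]

    @property
    def leaves(self) -> list[int]:
        return [i for i, d in enumerate(self.degrees) if d == 1]

    @property
    def branching_nodes(self) -> list[int]:
        return [i for i, d in enumerate(self.degrees) if d > 2]

    def is_tree(self) -> bool:
        if len(self.edges) != self.n_nodes - 1:
            return False
        # connectivity by BFS
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_nodes

    def copy(self) -> "PrincipalGraph":
        return PrincipalGraph(self.nodes.copy(), list(self.edges), self.params)

    def with_nodes(self, nodes: np.ndarray) -> "PrincipalGraph":
        return PrincipalGraph(np.asarray(nodes, float), list(self.edges), self.params)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes.tolist(),
            "edges": [list(e) for e in self.edges],
            "params": {"lam": self.params.lam, "mu": self.params.mu,
                       "alpha": self.params.alpha,
                       "r0": None if np.isinf(self.params.r0) else self.params.r0},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PrincipalGraph":
        p = d.get("params", {})
        params = ElasticParams(
            lam=p.get("lam", 0.05), mu=p.get("mu", 0.1), alpha=p.get("alpha", 0.01),
            r0=np.inf if p.get("r0") in (None, "inf") else float(p["r0"]),
        )
        return cls(np.asarray(d["nodes"], float), [tuple(e) for e in d["edges"]], params)

    @classmethod
    def from_json(cls, path: str | Path) -> "PrincipalGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FitReport:
    """Trace of a grammar-based fit: one energy entry per accepted step plus the seed."""

    energy_trace: list[EnergyBreakdown]
    step_candidate_energies: list[np.ndarray]
    final_n_nodes: int
    explained_variance: float
    partition: np.ndarray


# ---------------------------------------------------------------------------
# energy and partition


def _sq_dists(X: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(nodes**2, axis=1)[None, :]
        - 2.0 * X @ nodes.T
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def partition_points(
    X: np.ndarray, G: PrincipalGraph
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each point to its nearest node (ties to the lowest node index).

    Returns (labels, squared distance to the assigned node, trimmed mask);
    points farther than r0 from every node are flagged as trimmed.
    """
    X = np.asarray(X, dtype=float)
    d2 = _sq_dists(X, G.nodes)
    labels = np.argmin(d2, axis=1)
    best = d2[np.arange(len(X)), labels]
    trimmed = best > G.params.r0**2
    return labels, best, trimmed


def graph_energy(G: PrincipalGraph, X: np.ndarray) -> EnergyBreakdown:
    """Evaluate U = MSD + U_E + U_R for the current embedding."""
    if G.n_nodes == 0:
        raise ValueError("empty graph")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != G.dim:
        raise ValueError("data dimension does not match node embedding dimension")
    _, best, _ = partition_points(X, G)
    msd = float(np.mean(np.minimum(best, G.params.r0**2)))

    deg = G.degrees
    lam, mu, alpha = G.params.lam, G.params.mu, G.params.alpha
    u_e = 0.0
    for a, b in G.edges:
        pen = lam + alpha * (max(2, deg[a], deg[b]) - 2)
        diff = G.nodes[a] - G.nodes[b]
        u_e += pen * float(diff @ diff)

    adj = G.adjacency()
    u_r = 0.0
    for c in range(G.n_nodes):
        if deg[c] >= 2:
            diff = G.nodes[c] - G.nodes[adj[c]].mean(axis=0)
            u_r += mu * float(diff @ diff)
    return EnergyBreakdown(msd + u_e + u_r, msd, u_e, u_r)


# ---------------------------------------------------------------------------
# node-position optimization (splitting algorithm)


def _elastic_matrix(G: PrincipalGraph) -> np.ndarray:
    """Quadratic-form matrix of U_E + U_R in the node coordinates."""
    k = G.n_nodes
    deg = G.degrees
    lam, mu, alpha = G.params.lam, G.params.mu, G.params.alpha
    A = np.zeros((k, k))
    for a, b in G.edges:
        pen = lam + alpha * (max(2, deg[a], deg[b]) - 2)
        A[a, a] += pen
        A[b, b] += pen
        A[a, b] -= pen
        A[b, a] -= pen
    adj = G.adjacency()
    for c in range(k):
        d = deg[c]
        if d >= 2:
            u = np.zeros(k)
            u[c] = 1.0
            for nb in adj[c]:
                u[nb] -= 1.0 / d
            A += mu * np.outer(u, u)
    return A


def fit_node_positions(
    G: PrincipalGraph,
    X: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[PrincipalGraph, list[EnergyBreakdown]]:
    """Optimize node positions at fixed topology by alternating minimization.

    Each iteration (a) partitions points to nearest nodes and (b) solves the
    quadratic problem exactly for all node coordinates at that partition.  The
    total energy is non-increasing; iteration stops when the relative change
    of U falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    G = G.copy()
    n = len(X)
    A_el = _elastic_matrix(G)
    trace = [graph_energy(G, X)]
    for _ in range(max_iter):
        labels, _, trimmed = partition_points(X, G)
        use = ~trimmed
        counts = np.bincount(labels[use], minlength=G.n_nodes).astype(float)
        A = A_el + np.diag(counts / n)
        B = np.zeros((G.n_nodes, G.dim))
        np.add.at(B, labels[use], X[use] / n)
        try:
            new_nodes = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular node-position system (empty graph regions?): {exc}"
            )
        G.nodes = new_nodes
        trace.append(graph_energy(G, X))
        prev, cur = trace[-2].U, trace[-1].U
        if abs(prev - cur) <= tol * max(abs(prev), 1e-30):
            break
    return G, trace


# ---------------------------------------------------------------------------
# topological grammar


def _seed_graph(X: np.ndarray, params: ElasticParams) -> PrincipalGraph:
    """Deterministic two-node seed along the first principal direction."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    scale = 0.5 * float(np.std(centered @ pc1))
    if scale == 0:
        scale = 1e-6
    nodes = np.vstack([mean - scale * pc1, mean + scale * pc1])
    return PrincipalGraph(nodes, [(0, 1)], params)


def _candidates(
    G: PrincipalGraph, X: np.ndarray, rng: np.random.Generator
) -> list[PrincipalGraph]:
    """All graphs reachable by one grammar operation, deterministic order.

    "Add a node to a node" appends a leaf at the parent's position offset by
    the mean displacement of the parent's assigned points (seeded jitter along
    the dominant local direction when the cluster is empty); "bisect an edge"
    inserts the edge midpoint.
    """
    labels, _, trimmed = partition_points(X, G)
    edge_len = (
        np.median([np.linalg.norm(G.nodes[a] - G.nodes[b]) for a, b in G.edges])
        if G.edges
        else 1.0
    )
    out: list[PrincipalGraph] = []
    for j in range(G.n_nodes):  # add node to node
        pts = X[(labels == j) & ~trimmed]
        if len(pts):
            offset = pts.mean(axis=0) - G.nodes[j]
            if np.allclose(offset, 0):
                offset = 0.1 * edge_len * _unit(rng.standard_normal(G.dim))
        else:
            offset = 0.1 * edge_len * _unit(rng.standard_normal(G.dim))
        nodes = np.vstack([G.nodes, G.nodes[j] + offset])
        out.append(PrincipalGraph(nodes, G.edges + [(j, G.n_nodes)], G.params))
    for idx, (a, b) in enumerate(G.edges):  # bisect edge
        mid = 0.5 * (G.nodes[a] + G.nodes[b])
        nodes = np.vstack([G.nodes, mid])
        edges = [e for i, e in enumerate(G.edges) if i != idx]
        edges += [(a, G.n_nodes), (b, G.n_nodes)]
        out.append(PrincipalGraph(nodes, edges, G.params))
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def grow_tree(
    X: np.ndarray,
    n_nodes: int = 50,
    params: ElasticParams | None = None,
    seed: int = 0,
    candidate_tol: float = 1e-4,
    candidate_max_iter: int = 20,
    final_tol: float = 1e-6,
    final_max_iter: int = 200,
) -> tuple[PrincipalGraph, FitReport]:
    """Learn an elastic principal tree by greedy grammar search.

    From the two-node seed, each growth step refits every single-operation
    candidate structure (cheap inner loops) and accepts the one with minimal
    total energy, until ``n_nodes`` nodes are reached; the accepted graph is
    then polished with tight tolerances.  The result is a tree by construction
    (both grammar operations preserve acyclicity and connectivity).
    """
    X = np.asarray(X, dtype=float)
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if len(X) < n_nodes:
        raise ValueError("need at least n_nodes data points")
    params = params or ElasticParams()
    rng = np.random.default_rng(seed)

    G, _ = fit_node_positions(_seed_graph(X, params), X, candidate_tol, candidate_max_iter)
    trace = [graph_energy(G, X)]
    step_energies: list[np.ndarray] = []
    while G.n_nodes < n_nodes:
        cands = _candidates(G, X, rng)
        fitted = []
        energies = np.empty(len(cands))
        for i, cand in enumerate(cands):
            fit, tr = fit_node_positions(cand, X, candidate_tol, candidate_max_iter)
            fitted.append(fit)
            energies[i] = tr[-1].U
        best = int(np.argmin(energies))  # ties: lowest candidate index
        G = fitted[best]
        step_energies.append(energies)
        trace.append(graph_energy(G, X))
    G, polish = fit_node_positions(G, X, final_tol, final_max_iter)
    trace[-1] = polish[-1]
    labels, _, _ = partition_points(X, G)
    report = FitReport(
        energy_trace=trace,
        step_candidate_energies=step_energies,
        final_n_nodes=G.n_nodes,
        explained_variance=explained_variance(G, X),
        partition=labels,
    )
    return G, report


# ---------------------------------------------------------------------------
# post-processing


def _remove_node(G: PrincipalGraph, node: int) -> PrincipalGraph:
    keep = [i for i in range(G.n_nodes) if i != node]
    remap = {old: new for new, old in enumerate(keep)}
    edges = [
        (remap[a], remap[b]) for a, b in G.edges if a != node and b != node
    ]
    return PrincipalGraph(G.nodes[keep], edges, G.params)


def prune_tree(G: PrincipalGraph) -> PrincipalGraph:
    """Remove terminal segments that consist of a single edge.

    A leaf directly attached to a branching node (degree >= 3) is a one-edge
    stub left over from grammar growth; such leaves are removed one at a time
    (lowest index first, degrees re-evaluated after each removal) until none
    remain.  If pruning removes all branching structure a warning is emitted
    and the surviving path is returned.
    """
    G = G.copy()
    had_branching = bool(G.branching_nodes)
    while True:
        deg = G.degrees
        adj = G.adjacency()
        stub = next(
            (i for i in range(G.n_nodes) if deg[i] == 1 and deg[adj[i][0]] >= 3),
            None,
        )
        if stub is None:
            break
        G = _remove_node(G, stub)
    if had_branching and not G.branching_nodes:
        warnings.warn("pruning removed all branchings; returning the remaining path")
    return G


def extend_leaves(G: PrincipalGraph, X: np.ndarray) -> PrincipalGraph:
    """Extrapolate terminal edges so extreme points project onto edge interiors.

    Each leaf is moved outward along its terminal edge direction to the
    orthogonal projection, onto that ray, of the farthest point assigned to
    the leaf.  Leaves with no assigned points (or none beyond the current
    position) are left unchanged.
    """
    X = np.asarray(X, dtype=float)
    G = G.copy()
    labels, _, trimmed = partition_points(X, G)
    deg = G.degrees
    adj = G.adjacency()
    for leaf in range(G.n_nodes):
        if deg[leaf] != 1:
            continue
        pts = X[(labels == leaf) & ~trimmed]
        if len(pts) == 0:
            continue
        parent = adj[leaf][0]
        direction = G.nodes[leaf] - G.nodes[parent]
        length = np.linalg.norm(direction)
        if length == 0:
            continue
        d = direction / length
        t_max = float(np.max((pts - G.nodes[parent]) @ d))
        if t_max > length:
            G.nodes[leaf] = G.nodes[parent] + t_max * d
    return G


# ---------------------------------------------------------------------------
# projection onto the piecewise-linear graph


def project_points(X: np.ndarray, G: PrincipalGraph) -> list[Projection]:
    """Project each row of X onto the graph (nodes + linear edge segments).

    The fraction eps is clamped to [0, 1]; ties across edges go to the lowest
    edge index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    n_e = len(G.edges)
    if n_e == 0:
        raise ValueError("graph has no edges to project onto")
    eps = np.empty((n, n_e))
    res = np.empty((n, n_e))
    for k, (a, b) in enumerate(G.edges):
        pa, pb = G.nodes[a], G.nodes[b]
        d = pb - pa
        denom = float(d @ d)
        t = ((X - pa) @ d) / denom if denom > 0 else np.zeros(n)
        t = np.clip(t, 0.0, 1.0)
        proj = pa[None, :] + t[:, None] * d[None, :]
        eps[:, k] = t
        res[:, k] = np.sum((X - proj) ** 2, axis=1)
    best = np.argmin(res, axis=1)
    out = []
    for i in range(n):
        k = int(best[i])
        a, b = G.edges[k]
        point = G.nodes[a] + eps[i, k] * (G.nodes[b] - G.nodes[a])
        out.append(Projection(k, float(eps[i, k]), point, float(res[i, k])))
    return out


def project_point(x: np.ndarray, G: PrincipalGraph) -> Projection:
    """Projection of a single vector onto the graph."""
    return project_points(np.atleast_2d(x), G)[0]


def explained_variance(G: PrincipalGraph, X: np.ndarray) -> float:
    """Fraction of total variance captured by projection onto the graph.

    1 - (sum of squared projection residuals) / (total sum of squares about
    the data mean).
    """
    X = np.asarray(X, dtype=float)
    total = float(np.sum((X - X.mean(axis=0)) ** 2))
    if total == 0:
        raise ValueError("data have zero total variance")
    resid = sum(p.sq_residual for p in project_points(X, G))
    return 1.0 - resid / total
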
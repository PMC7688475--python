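"""Metro-map style 2-D visualization of a principal tree and its data.

The embedded tree is flattened with the Kamada-Kawai stress-minimizing
layout, using Euclidean edge lengths in data space as target graph
distances.  Each observation is then drawn at its projection abscissa on the
embedded edge and displaced perpendicularly, on a seeded random side, by an
amount proportional to its projection residual in the original space; the
proportionality constant is the *scattering* parameter.  Edge widths can
encode the local trend of any numeric variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import PrincipalGraph, partition_points, project_points

__all__ = [
    "GraphLayout",
    "PointLayout",
    "layout_graph",
    "place_points",
    "edge_trend",
    "node_class_proportions",
]


@dataclass
class GraphLayout:
    """2-D node coordinates of the embedded graph."""

    coordinates: np.ndarray  # (K, 2)
    seed: int

    def edge_segment(self, G: PrincipalGraph, edge_index: int) -> tuple[np.ndarray, np.ndarray]:
        a, b = G.edges[edge_index]
        return self.coordinates[a], self.coordinates[b]


@dataclass
class PointLayout:
    """2-D observation placement around the embedded tree."""

    table: pd.DataFrame  # x, y, edge, side, residual
    scattering: float
    seed: int


def _nx_graph(G: PrincipalGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(G.n_nodes))
    for a, b in G.edges:
        g.add_edge(a, b, weight=float(np.linalg.norm(G.nodes[a] - G.nodes[b])) or 1e-9)
    return g


def layout_graph(G: PrincipalGraph, seed: int = 0) -> GraphLayout:
    """Kamada-Kawai 2-D embedding of the graph (deterministic given seed).

    Pairwise 2-D distances approximate graph geodesic distances weighted by
    data-space edge lengths.  Disconnected graphs are laid out per component
    and tiled horizontally.
    """
    g = _nx_graph(G)
    coords = np.zeros((G.n_nodes, 2))
    offset = 0.0
    for comp in sorted(nx.connected_components(g), key=min):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            pos = {next(iter(comp)): np.zeros(2)}
        else:
            init = nx.circular_layout(sub)  # deterministic start
            pos = nx.kamada_kawai_layout(sub, pos=init, weight="weight")
        arr = np.array([pos[i] for i in sorted(comp)])
        arr = arr - arr.min(axis=0)
        for i, node in enumerate(sorted(comp)):
            coords[node] = arr[i] + np.array([offset, 0.0])
        offset += arr[:, 0].max() + 1.0 if len(comp) > 1 else 1.0
    return GraphLayout(coordinates=coords, seed=seed)


def place_points(
    X: np.ndarray,
    G: PrincipalGraph,
    layout: GraphLayout,
    scattering: float | None = None,
    seed: int = 0,
) -> PointLayout:
    """Place observations around the embedded tree.

    Each point sits at its projection abscissa on the embedded edge and is
    displaced perpendicular to it by ``scattering x residual`` on a random
    (seeded) side.  The default scattering makes the median displacement
    equal to 25% of the median embedded edge length.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    projs = project_points(X, G)
    residuals = np.sqrt([p.sq_residual for p in projs])
    edge_lengths = np.array([
        np.linalg.norm(layout.coordinates[a] - layout.coordinates[b]) for a, b in G.edges
    ])
    if scattering is None:
        med_res = float(np.median(residuals))
        med_len = float(np.median(edge_lengths)) if len(edge_lengths) else 1.0
        scattering = 0.25 * med_len / med_res if med_res > 0 else 1.0
    rng = np.random.default_rng(seed)
    sides = rng.choice([-1.0, 1.0], size=len(X))
    xy = np.empty((len(X), 2))
    edges = np.empty(len(X), dtype=int)
    for i, p in enumerate(projs):
        a, b = G.edges[p.edge]
        pa, pb = layout.coordinates[a], layout.coordinates[b]
        base = pa + p.eps * (pb - pa)
        d = pb - pa
        norm = np.linalg.norm(d)
        perp = np.array([-d[1], d[0]]) / norm if norm > 0 else np.zeros(2)
        xy[i] = base + sides[i] * scattering * residuals[i] * perp
        edges[i] = p.edge
    table = pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "edge": edges, "side": sides, "residual": residuals}
    )
    return PointLayout(table=table, scattering=float(scattering), seed=seed)


def edge_trend(G: PrincipalGraph, X: np.ndarray, var) -> np.ndarray:
    """Per-edge mean of a variable over the points projected onto it.

    Empty edges are interpolated from the means of their incident nodes
    (nearest-node assignment; global mean as last resort).  The result is
    min-max normalized to [0, 1] for width encoding; a constant variable
    yields equal widths (all 0.5).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    v = np.asarray(var, dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("variable has no observed values")
    global_mean = float(v[ok].mean())
    projs = project_points(X, G)
    edge_of = np.array([p.edge for p in projs])
    means = np.full(len(G.edges), np.nan)
    for e in range(len(G.edges)):
        sel = (edge_of == e) & ok
        if sel.any():
            means[e] = v[sel].mean()
    if np.isnan(means).any():
        labels, _, _ = partition_points(X, G)
        node_means = np.full(G.n_nodes, np.nan)
        for j in range(G.n_nodes):
            sel = (labels == j) & ok
            if sel.any():
                node_means[j] = v[sel].mean()
        node_means = np.where(np.isnan(node_means), global_mean, node_means)
        for e in np.where(np.isnan(means))[0]:
            a, b = G.edges[e]
            means[e] = 0.5 * (node_means[a] + node_means[b])
    lo, hi = means.min(), means.max()
    if hi == lo:
        return np.full(len(means), 0.5)
    return (means - lo) / (hi - lo)


def node_class_proportions(X: np.ndarray, G: PrincipalGraph, class_labels) -> pd.DataFrame:
    """Per-node class proportions (pie-chart summaries) and point counts."""
    labels, _, _ = partition_points(np.asarray(X, float), G)
    cl = np.asarray(class_labels)
    classes = np.unique(cl)
    rows = []
    for j in range(G.n_nodes):
        sel = labels == j
        n = int(sel.sum())
        props = [float(np.mean(cl[sel] == c)) if n else 0.0 for c in classes]
        rows.append([j, n, *props])
    return pd.DataFrame(rows, columns=["node", "count", *[str(c) for c in classes]]).set_index("node")
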
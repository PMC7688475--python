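"""Seeded generators of branching mixed-type datasets with known ground truth.

The generator emulates the geometric model assumed throughout the package:
observations condensed along the arms of a tree embedded in R^m, each point a
uniform draw along an arm plus isotropic Gaussian noise, with its true branch
label and arc-length pseudo-time (geodesic distance from the root along the
embedded tree) recorded before any degradation.  Columns can then be degraded
to ordinal or binary variables by binning — mimicking how clinical scales
discretize latent quantities — and missingness can be injected either
uniformly at random or concentrated in chosen columns, reproducing the
non-random missingness patterns of real clinical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MixedDataset, VariableMeta

__all__ = [
    "TreeSpec",
    "star_tree_spec",
    "generate_branching_dataset",
    "degrade_to_mixed",
    "inject_missing",
    "continuous_dataset",
]


@dataclass
class TreeSpec:
    """Blueprint of an embedded noisy tree.

    topology : edge list over abstract node ids (must form a tree; node 0 is
        the root used for arc-length pseudo-time).
    arm_lengths : length of each arm, aligned with ``topology`` (default 1.0).
    dim : embedding dimension m.
    noise : isotropic Gaussian noise s.d. (same units as arm lengths).
    points_per_branch : observations sampled per arm.
    node_positions : optional explicit (n_nodes, dim) embedding; otherwise
        arm directions are drawn at random with sibling arms kept apart.
    """

    topology: list[tuple[int, int]]
    arm_lengths: list[float] | None = None
    dim: int = 3
    noise: float = 0.05
    points_per_branch: int = 100
    node_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_nodes = max(max(e) for e in self.topology) + 1
        if len(self.topology) != n_nodes - 1:
            raise ValueError("topology must be a tree (n_edges = n_nodes - 1)")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.arm_lengths is None:
            self.arm_lengths = [1.0] * len(self.topology)
        if len(self.arm_lengths) != len(self.topology):
            raise ValueError("arm_lengths must align with topology")

    @property
    def n_nodes(self) -> int:
        return max(max(e) for e in self.topology) + 1


def star_tree_spec(n_arms: int, **kwargs) -> TreeSpec:
    """A star: one center (node 0) with ``n_arms`` unit arms."""
    return TreeSpec(topology=[(0, i + 1) for i in range(n_arms)], **kwargs)


def bifurcating_tree_spec(n_arms: int, **kwargs) -> TreeSpec:
    """A tree with ``n_arms`` terminal arms built from bifurcations only.

    Up to 3 arms this is a star (the single branching has degree <= 3); for
    4 arms two degree-3 branchings joined by an internal arm carry two
    terminal arms each.  Degree-3 branchings are the generic geometry of
    diverging disease trajectories; a higher-order star is available through
    an explicit :class:`TreeSpec` topology.
    """
    if n_arms < 2:
        raise ValueError("need >= 2 arms")
    if n_arms <= 3:
        return star_tree_spec(n_arms, **kwargs)
    if n_arms == 4:
        return TreeSpec(topology=[(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)], **kwargs)
    raise ValueError("bifurcating fixtures are provided for 2-4 arms")


def _embed_nodes(spec: TreeSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.node_positions is not None:
        pos = np.asarray(spec.node_positions, dtype=float)
        if pos.shape != (spec.n_nodes, spec.dim):
            raise ValueError("node_positions shape mismatch")
        return pos
    pos = np.zeros((spec.n_nodes, spec.dim))
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), ln in zip(spec.topology, spec.arm_lengths):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))
    placed = {0}
    used_dirs: dict[int, list[np.ndarray]] = {}
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for nb, ln in adj.get(cur, []):
            if nb in placed:
                continue
            # arms leaving one node must be well separated or the declared
            # branching is not geometrically realized: among random candidate
            # directions keep the one farthest (max-min angle) from the
            # directions already used at this node
            cands = rng.standard_normal((100, spec.dim))
            cands /= np.linalg.norm(cands, axis=1, keepdims=True)
            used = used_dirs.get(cur, [])
            if used:
                worst_cos = np.max(np.abs(cands @ np.array(used).T), axis=1)
                d = cands[int(np.argmin(worst_cos))]
            else:
                d = cands[0]
            used_dirs.setdefault(cur, []).append(d)
            used_dirs.setdefault(nb, []).append(-d)
            pos[nb] = pos[cur] + ln * d
            placed.add(nb)
            queue.append(nb)
    return pos


def generate_branching_dataset(
    spec: TreeSpec, seed: int = 0
) -> tuple[MixedDataset, pd.DataFrame]:
    """Sample points along the embedded tree arms, with ground truth.

    Points are uniform along each arm plus isotropic N(0, noise^2) noise.
    Returns an all-continuous :class:`MixedDataset` and a truth frame with
    the branch (arm) label and arc-length pseudo-time from node 0, recorded
    before the noise-free coordinates are perturbed.
    """
    rng = np.random.default_rng(seed)
    pos = _embed_nodes(spec, rng)
    # arc length from root (node 0) along the abstract tree
    dist = {0: 0.0}
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), ln in zip(spec.topology, spec.arm_lengths):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for nb, ln in adj.get(cur, []):
            if nb not in dist:
                dist[nb] = dist[cur] + ln
                queue.append(nb)
    xs, branch, ptime = [], [], []
    for bidx, ((a, b), ln) in enumerate(zip(spec.topology, spec.arm_lengths)):
        t = rng.uniform(0.0, 1.0, size=spec.points_per_branch)
        base = pos[a][None, :] + t[:, None] * (pos[b] - pos[a])[None, :]
        xs.append(base + rng.normal(0.0, spec.noise, size=base.shape))
        branch.extend([bidx] * spec.points_per_branch)
        # pseudo-time accumulates toward the endpoint farther from the root
        if dist[a] <= dist[b]:
            ptime.extend(dist[a] + t * ln)
        else:
            ptime.extend(dist[b] + (1.0 - t) * ln)
    X = np.vstack(xs)
    truth = pd.DataFrame({"branch": branch, "pseudotime": ptime})
    ds = continuous_dataset(X)
    return ds, truth


def continuous_dataset(X: np.ndarray, prefix: str = "x") -> MixedDataset:
    """Wrap a numeric matrix as an all-continuous MixedDataset."""
    X = np.asarray(X, dtype=float)
    names = [f"{prefix}{j}" for j in range(X.shape[1])]
    values = pd.DataFrame(X, columns=names)
    mask = pd.DataFrame(False, index=values.index, columns=names)
    meta = [VariableMeta(name=n, kind="continuous") for n in names]
    return MixedDataset(values=values, missing_mask=mask, meta=meta)


def degrade_to_mixed(
    X: np.ndarray | pd.DataFrame,
    plan: dict[int, dict],
) -> MixedDataset:
    """Degrade selected numeric columns to ordinal/binary by binning.

    ``plan`` maps column index -> {'kind': 'ordinal'|'binary',
    'bins': strictly increasing interior bin edges} (a binary column takes a
    single threshold).  Level order preserves numeric order; untouched
    columns stay continuous.
    """
    arr = np.asarray(X, dtype=float)
    n, p = arr.shape
    values: dict[str, pd.Series] = {}
    meta: list[VariableMeta] = []
    for j in range(p):
        name = f"x{j}"
        if j in plan:
            entry = plan[j]
            edges = np.asarray(entry["bins"], dtype=float)
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be strictly increasing")
            kind = entry.get("kind", "ordinal")
            codes = np.digitize(arr[:, j], edges)
            n_levels = len(edges) + 1
            counts = np.bincount(codes, minlength=n_levels)
            if (counts == 0).any():
                warnings.warn(f"column {name}: some bins cover no data")
            if kind == "binary" and n_levels != 2:
                raise ValueError("binary degradation takes exactly one threshold")
            levels = tuple(str(k) for k in range(n_levels))
            values[name] = pd.Series(codes.astype(str))
            meta.append(VariableMeta(name=name, kind=kind, levels=levels))
        else:
            values[name] = pd.Series(arr[:, j])
            meta.append(VariableMeta(name=name, kind="continuous"))
    df = pd.DataFrame(values)
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    return MixedDataset(values=df, missing_mask=mask, meta=meta)


def inject_missing(
    ds: MixedDataset,
    mechanism: str = "uniform",
    fraction: float = 0.05,
    seed: int = 0,
    columns: list[str] | None = None,
) -> MixedDataset:
    """Blank out cells uniformly at random or concentrated in chosen columns.

    ``uniform``: each cell is independently missing with probability
    ``fraction``.  ``column_block``: only the listed columns are affected,
    each of their cells missing with probability ``fraction``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    mask = ds.missing_mask.copy()
    if mechanism == "uniform":
        hit = rng.random(values.shape) < fraction
    elif mechanism == "column_block":
        if not columns:
            raise ValueError("column_block mechanism requires target columns")
        hit = np.zeros(values.shape, dtype=bool)
        for c in columns:
            hit[:, values.columns.get_loc(c)] = rng.random(len(values)) < fraction
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    values = values.astype(object)
    values[pd.DataFrame(hit, index=values.index, columns=values.columns)] = np.nan
    mask = mask | pd.DataFrame(hit, index=mask.index, columns=mask.columns)
    return MixedDataset(values=values, missing_mask=mask, meta=list(ds.meta),
                        row_ids=list(ds.row_ids))
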
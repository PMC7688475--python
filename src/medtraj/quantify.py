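"""Quantification of mixed-type tables into fully numeric matrices.

Ordinal (and binary) variables are scored under a latent-Gaussian model: the
observed levels are assumed to arise by binning a standard-normal latent
variable, so level *i* with empirical proportion ``p_i`` receives the normal
quantile of the midpoint of its cumulative-probability interval,

    x_i = Phi^-1( sum_{j<i} p_j + p_i / 2 ).

Categorical variables are one-hot ("dummy") encoded.  When several ordinal
variables are present they can additionally be rescored jointly by *optimal
scaling*: alternating updates that maximize the sum of squared pairwise
correlations among all numeric columns while keeping each level-to-score map
monotone.  Finally, columns are standardized to z-scores and optionally
projected onto leading principal components, with a scree-based heuristic for
the intrinsic dimension (count of covariance eigenvalues above lambda_0 / C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression

from .datasets import MixedDataset, VariableMeta

__all__ = [
    "QuantificationMap",
    "QuantifiedMatrix",
    "quantify_ordinal_univariate",
    "dummy_encode",
    "quantify_dataset",
    "optimal_scaling",
    "zscore",
    "estimate_intrinsic_dimension_pca",
    "reduce_dimension",
]

_EPS = 1e-12


@dataclass(frozen=True)
class QuantificationMap:
    """Level scores for one ordinal/binary variable."""

    name: str
    levels: tuple[str, ...]
    counts: np.ndarray
    scores: np.ndarray

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def apply(self, values: pd.Series) -> pd.Series:
        lut = {lvl: s for lvl, s in zip(self.levels, self.scores)}
        return values.map(lambda v: lut.get(v, np.nan) if isinstance(v, str) else np.nan)


@dataclass
class QuantifiedMatrix:
    """Fully numeric observation × variable grid with column provenance.

    ``provenance`` maps each numeric column to its source variable (and dummy
    level, if any); ``maps`` holds the level-score tables of ordinal/binary
    columns; ``center``/``scale`` store z-scoring constants once applied.
    """

    data: pd.DataFrame
    provenance: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    maps: dict[str, QuantificationMap] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.data.columns:
            self.provenance.setdefault(c, (c, None))
            self.kinds.setdefault(c, "continuous")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "QuantifiedMatrix":
        return QuantifiedMatrix(
            data=self.data.copy(),
            provenance=dict(self.provenance),
            maps=dict(self.maps),
            kinds=dict(self.kinds),
            center=dict(self.center),
            scale=dict(self.scale),
        )

    def dummy_groups(self) -> dict[str, list[str]]:
        """Columns grouped by categorical source variable (dummy blocks)."""
        groups: dict[str, list[str]] = {}
        for col, (src, lvl) in self.provenance.items():
            if lvl is not None:
                groups.setdefault(src, []).append(col)
        return groups


# ---------------------------------------------------------------------------
# univariate quantification


def quantify_ordinal_univariate(counts: Sequence[float]) -> np.ndarray:
    """Normal-quantile scores of ordered levels from their counts.

    Level *i* receives ``Phi^-1(cum_{<i} + p_i/2)`` where ``p_i`` is the level
    proportion.  Zero-count levels get the quantile at their (zero-width)
    cumulative position, with the argument clipped away from 0 and 1.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all counts are zero; nothing to quantify")
    p = c / total
    midpoints = np.cumsum(p) - p / 2.0
    return norm.ppf(np.clip(midpoints, _EPS, 1.0 - _EPS))


def dummy_encode(
    values: pd.Series,
    levels: Sequence[str],
    drop_first: bool = False,
    missing: pd.Series | None = None,
) -> pd.DataFrame:
    """One-hot encode a categorical column into binary indicator columns.

    A missing source entry yields missing values in every derived column.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("dummy encoding requires >= 2 levels")
    keep = levels[1:] if drop_first else levels
    if missing is None:
        missing = values.isna()
    out = {}
    for lvl in keep:
        col = (values.astype(object) == lvl).astype(float)
        col[missing.to_numpy()] = np.nan
        out[f"{values.name}={lvl}"] = col
    return pd.DataFrame(out, index=values.index)


def quantify_dataset(
    ds: MixedDataset,
    drop_first: bool = False,
    roles: Sequence[str] = ("feature", "outcome"),
) -> QuantifiedMatrix:
    """Univariate quantification of a whole mixed dataset.

    Binary and ordinal columns get latent-Gaussian level scores (binary is the
    2-level special case), categorical columns are dummy encoded, continuous
    columns pass through.  Missing cells stay NaN for the imputation stage.
    """
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, tuple[str, str | None]] = {}
    maps: dict[str, QuantificationMap] = {}
    kinds: dict[str, str] = {}
    for m in ds.meta:
        if m.role not in roles:
            continue
        col = ds.values[m.name]
        mask = ds.missing_mask[m.name]
        if m.kind == "continuous":
            cols[m.name] = pd.to_numeric(col, errors="coerce")
            provenance[m.name] = (m.name, None)
            kinds[m.name] = "continuous"
        elif m.kind in ("binary", "ordinal"):
            observed = col[~mask.to_numpy()].astype(str)
            counts = np.array([(observed == lvl).sum() for lvl in m.levels], dtype=float)
            if counts.sum() == 0:
                raise ValueError(f"column {m.name!r} has no observed entries to quantify")
            qmap = QuantificationMap(m.name, m.levels, counts, quantify_ordinal_univariate(counts))
            maps[m.name] = qmap
            lut = dict(zip(qmap.levels, qmap.scores))
            num = col.astype(object).map(lambda v: lut.get(str(v), np.nan))
            num[mask.to_numpy()] = np.nan
            cols[m.name] = num.astype(float)
            provenance[m.name] = (m.name, None)
            kinds[m.name] = m.kind
        else:  # categorical
            dummies = dummy_encode(col.rename(m.name).astype(object), m.levels, drop_first, missing=mask)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol]
                provenance[dcol] = (m.name, dcol.split("=", 1)[1])
                kinds[dcol] = "binary"
    data = pd.DataFrame(cols, index=ds.values.index)
    return QuantifiedMatrix(data=data, provenance=provenance, maps=maps, kinds=kinds)


# ---------------------------------------------------------------------------
# optimal scaling


def _pairwise_corr_objective(arr: np.ndarray) -> float:
    """J = sum over unordered column pairs of squared Pearson correlation."""
    sd = arr.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    c = np.corrcoef(arr[:, keep], rowvar=False)
    p = c.shape[0]
    return float((np.sum(c**2) - p) / 2.0)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu, sd = x.mean(), x.std()
    return (x - mu) / sd if sd > 0 else x - mu


def optimal_scaling(
    qm: QuantifiedMatrix,
    ordinal_columns: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[QuantifiedMatrix, list[float]]:
    """Jointly rescore ordinal columns to maximize summed squared correlations.

    Alternating update: cycling over ordinal columns, each column's target is
    the first principal direction of the other standardized columns; per-level
    target means are mapped through isotonic regression (both monotone
    directions tried, the non-decreasing score map retained) and the candidate
    scores are kept only if the objective does not decrease, so the returned
    trace is monotone non-decreasing by construction.  Requires complete data
    in the involved columns.  Returns the rescored matrix (involved columns
    standardized to mean 0, variance 1) and the objective trace per sweep.
    """
    out = qm.copy()
    if ordinal_columns is None:
        ordinal_columns = [c for c, k in out.kinds.items() if k in ("ordinal", "binary") and c in out.maps]
    ordinal_columns = [c for c in ordinal_columns if c in out.columns]
    arr = out.data.to_numpy(dtype=float).copy()
    if np.isnan(arr).any():
        raise ValueError("optimal scaling requires complete data; impute first")
    colindex = {c: i for i, c in enumerate(out.columns)}

    active = []
    for c in ordinal_columns:
        j = colindex[c]
        if arr[:, j].std() == 0:
            warnings.warn(f"constant column {c!r} excluded from optimal scaling")
            continue
        active.append(c)
    # work on a standardized copy throughout
    for j in range(arr.shape[1]):
        arr[:, j] = _standardize(arr[:, j])

    # integer level codes per active ordinal column, recovered from the
    # (pre-standardization) level scores by nearest match
    codes: dict[str, np.ndarray] = {}
    for c in active:
        qmap = out.maps[c]
        vals = out.data[c].to_numpy(dtype=float)
        codes[c] = np.argmin(np.abs(vals[:, None] - qmap.scores[None, :]), axis=1)

    trace = [_pairwise_corr_objective(arr)]
    new_scores: dict[str, np.ndarray] = {}
    converged = False
    for _ in range(max_iter):
        for c in active:
            j = colindex[c]
            others = np.delete(np.arange(arr.shape[1]), j)
            if len(others) == 0:
                continue
            sub = arr[:, others]
            # first principal direction of the other columns
            target = PCA(n_components=1, svd_solver="full").fit_transform(sub)[:, 0]
            lv = codes[c]
            nlev = lv.max() + 1
            means = np.array([target[lv == k].mean() if (lv == k).any() else np.nan for k in range(nlev)])
            wts = np.array([(lv == k).sum() for k in range(nlev)], dtype=float)
            ok = ~np.isnan(means)
            order = np.arange(nlev)[ok]
            best = None
            for increasing in (True, False):
                iso = IsotonicRegression(increasing=increasing)
                fit = iso.fit_transform(order, means[ok], sample_weight=wts[ok])
                scores = fit if increasing else -fit  # keep the map non-decreasing
                col = scores[np.searchsorted(order, lv)]
                if col.std() == 0:
                    continue
                cand = arr.copy()
                cand[:, j] = _standardize(col)
                jval = _pairwise_corr_objective(cand)
                if best is None or jval > best[0]:
                    full = np.full(nlev, np.nan)
                    full[ok] = scores
                    best = (jval, cand[:, j], full)
            if best is not None and best[0] >= trace[-1] - 1e-12:
                arr[:, j] = best[1]
                new_scores[c] = best[2]
        trace.append(_pairwise_corr_objective(arr))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("optimal scaling did not converge within max_iter; returning best iterate")

    for c in active:
        j = colindex[c]
        out.data[c] = arr[:, j]
        if c in new_scores:
            qmap = out.maps[c]
            out.maps[c] = QuantificationMap(qmap.name, qmap.levels, qmap.counts, new_scores[c])
    return out, trace


# ---------------------------------------------------------------------------
# z-scoring and PCA


def zscore(qm: QuantifiedMatrix) -> QuantifiedMatrix:
    """Center and scale every column to mean 0, variance 1 (population 1/N).

    Zero-variance columns are left at 0 with a warning; the constants are
    stored on the result for inverse transforms.
    """
    out = qm.copy()
    arr = out.data.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("z-scoring requires complete data; impute first")
    for i, c in enumerate(out.columns):
        mu = float(arr[:, i].mean())
        sd = float(arr[:, i].std())  # population convention (ddof=0)
        if sd == 0:
            warnings.warn(f"zero-variance column {c!r} left at 0 after centering")
            sd_used = 1.0
        else:
            sd_used = sd
        out.data[c] = (arr[:, i] - mu) / sd_used
        out.center[c] = mu
        out.scale[c] = sd_used
    return out


def _as_array(qm) -> np.ndarray:
    if isinstance(qm, QuantifiedMatrix):
        return qm.values
    return np.asarray(qm, dtype=float)


def estimate_intrinsic_dimension_pca(qm, C: float = 10.0) -> int:
    """Scree-based intrinsic dimension: eigenvalues above lambda_0 / C.

    Counts covariance eigenvalues exceeding the largest eigenvalue divided by
    the tolerated condition number ``C`` (default 10).
    """
    arr = _as_array(qm)
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 rows to estimate a covariance spectrum")
    centered = arr - arr.mean(axis=0)
    ev = np.linalg.eigvalsh(np.cov(centered, rowvar=False, ddof=0))[::-1]
    lam0 = ev[0]
    if lam0 <= 0:
        return 0
    return int(np.sum(ev > lam0 / C))


def reduce_dimension(qm, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA projection onto the leading components of the centered data.

    Returns (scores, loadings, explained-variance fractions).
    """
    arr = _as_array(qm)
    if n_components > arr.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds number of columns {arr.shape[1]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(arr)
    return scores, pca.components_, pca.explained_variance_ratio_
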
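"""Association of variables with tree segments and trajectories.

Segment labels form a categorical partition of the observations, so a
categorical/binary variable is tested against segments with the standard
independence chi-square test; cells that depart from independence are ranked
by the deviation score

    Deviation(value j, segment i) = (E_ij - O_ij) / E_ij,

the relative difference between expected and observed counts (note the sign:
positive values mean the observed count falls short of expectation).  Numeric
and ordinal variables are tested with one-way ANOVA on one-hot segment
indicators; per-segment effects are linear-model coefficients relative to the
largest segment.

Along a single trajectory, a variable is associated with disease progression
through a regression on pseudo-time: Gaussian-kernel (Nadaraya-Watson)
regression for continuous/ordinal variables and logistic regression for
binary ones, scored by R^2.  ``screen_associations`` runs all tests, applies
Benjamini-Hochberg correction across variables and returns long-format
tables of the retained pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SegmentAssociation",
    "TrajectoryAssociation",
    "segment_chi2",
    "segment_anova",
    "trajectory_regression",
    "screen_associations",
]


@dataclass
class SegmentAssociation:
    """Result of one variable-versus-segments test."""

    variable: str
    test: str  # chi2 | anova
    statistic: float
    p_value: float
    effects: pd.DataFrame  # chi2: deviation per (segment, level); anova: coef, p per segment
    adjusted_p: float | None = None
    flag: str | None = None


@dataclass
class TrajectoryAssociation:
    """Regression of one variable on pseudo-time along one trajectory."""

    variable: str
    trajectory: int
    kind: str  # kernel | logistic
    r2: float
    grid: np.ndarray
    curve: np.ndarray
    flag: str | None = None


# ---------------------------------------------------------------------------
# segment tests


def segment_chi2(segment_labels, values, variable: str = "var") -> SegmentAssociation:
    """Independence chi-square of a categorical variable against segments.

    Missing variable entries are excluded pairwise.  ``effects`` holds the
    (E - O) / E deviation per (segment, level) cell; cells with zero expected
    count are undefined (NaN) and flagged.
    """
    seg = pd.Series(np.asarray(segment_labels), name="segment")
    val = pd.Series(np.asarray(values, dtype=object), name=variable)
    ok = ~pd.isna(val.to_numpy())
    seg, val = seg[ok], val[ok]
    table = pd.crosstab(seg, val)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 segments and >= 2 observed levels")
    chi2, p, _, expected = chi2_contingency(table.to_numpy())
    expected = np.asarray(expected, dtype=float)
    flag = None
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = (expected - table.to_numpy()) / expected
    if (expected == 0).any():
        deviation[expected == 0] = np.nan
        flag = "zero-expected cells; their deviation is undefined"
    effects = pd.DataFrame(deviation, index=table.index, columns=table.columns)
    return SegmentAssociation(variable, "chi2", float(chi2), float(p), effects, flag=flag)


def segment_anova(segment_labels, values, variable: str = "var") -> SegmentAssociation:
    """One-way ANOVA of a numeric variable on one-hot segment indicators.

    The largest segment is the reference; per-segment effects are linear-model
    coefficients (segment mean minus reference mean) with their p-values.
    Missing entries are excluded pairwise; a constant variable is flagged.
    """
    seg = np.asarray(segment_labels)
    val = np.asarray(values, dtype=float)
    ok = ~np.isnan(val)
    seg, val = seg[ok], val[ok]
    uniq, counts = np.unique(seg, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 segments with >= 2 observations each")
    if np.std(val) == 0:
        effects = pd.DataFrame({"coef": 0.0, "p": np.nan}, index=pd.Index(uniq, name="segment"))
        return SegmentAssociation(variable, "anova", np.nan, np.nan, effects,
                                  flag="constant variable; F undefined")
    reference = uniq[np.argmax(counts)]
    others = [u for u in uniq if u != reference]
    design = np.column_stack([np.ones(len(val))] + [(seg == u).astype(float) for u in others])
    fit = sm.OLS(val, design).fit()
    rows = {reference: (0.0, np.nan)}
    for i, u in enumerate(others):
        rows[u] = (float(fit.params[i + 1]), float(fit.pvalues[i + 1]))
    effects = pd.DataFrame(
        [(u, *rows[u]) for u in uniq], columns=["segment", "coef", "p"]
    ).set_index("segment")
    return SegmentAssociation(variable, "anova", float(fit.fvalue), float(fit.f_pvalue), effects)


# ---------------------------------------------------------------------------
# trajectory regressions


def _kernel_smooth(pt: np.ndarray, y: np.ndarray, at: np.ndarray, bandwidth: float) -> np.ndarray:
    w = np.exp(-0.5 * ((at[:, None] - pt[None, :]) / bandwidth) ** 2)
    denom = w.sum(axis=1)
    denom[denom == 0] = np.nan
    out = (w * y[None, :]).sum(axis=1) / denom
    return np.where(np.isnan(out), float(np.mean(y)), out)


def trajectory_regression(
    values,
    pt,
    kind: str = "kernel",
    bandwidth: float = 0.25,
    grid_size: int = 50,
    variable: str = "var",
    trajectory: int = 0,
) -> TrajectoryAssociation:
    """Regress a variable on pseudo-time along one trajectory.

    ``kind='kernel'`` (continuous/ordinal): Nadaraya-Watson regression with a
    Gaussian kernel of the given bandwidth (edge units); R^2 = 1 - SSres/SStot.
    ``kind='logistic'`` (binary): logistic regression of the outcome on
    pseudo-time; R^2 is the squared Pearson correlation between the fitted
    probability and the outcome.  The fitted curve is returned on a uniform
    pseudo-time grid.  A constant variable yields R^2 = 0; logistic separation
    falls back to a small ridge penalty and is flagged.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(pt, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(t))
    y, t = y[ok], t[ok]
    if len(y) < 10:
        raise ValueError("need >= 10 observations on the trajectory")
    grid = np.linspace(t.min(), t.max(), grid_size)
    flag = None
    if np.std(y) == 0:
        return TrajectoryAssociation(variable, trajectory, kind, 0.0, grid,
                                     np.full(grid_size, y[0]), flag="constant variable")
    if kind == "kernel":
        fitted = _kernel_smooth(t, y, t, bandwidth)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
        curve = _kernel_smooth(t, y, grid, bandwidth)
    elif kind == "logistic":
        yb = y.astype(int)
        tt = t.reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                model = LogisticRegression(penalty=None, max_iter=1000).fit(tt, yb)
            except Warning:
                model = LogisticRegression(C=1.0, max_iter=1000).fit(tt, yb)
                flag = "separation; ridge-penalized fit"
        prob = model.predict_proba(tt)[:, 1]
        if np.std(prob) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(prob, yb)[0, 1] ** 2)
        curve = model.predict_proba(grid.reshape(-1, 1))[:, 1]
    else:
        raise ValueError(f"unknown regression kind {kind!r}")
    return TrajectoryAssociation(variable, trajectory, kind, float(r2), grid, curve, flag)


# ---------------------------------------------------------------------------
# screening


def screen_associations(
    variables: pd.DataFrame,
    kinds: dict[str, str],
    segment_labels: np.ndarray,
    pseudotime_table,
    r2_threshold: float = 0.3,
    deviation_threshold: float = 0.3,
    coef_threshold: float = 0.3,
    fdr_level: float = 0.05,
    bandwidth: float = 0.25,
) -> dict[str, pd.DataFrame]:
    """Screen every variable against all segments and trajectories.

    Parameters
    ----------
    variables
        Numeric observation × variable frame (quantified values; binary
        columns coded 0/1 or two quantified levels).
    kinds
        Variable name -> {'binary','ordinal','continuous'}; binary columns
        get the chi-square segment test and logistic trajectory regression,
        the others ANOVA and kernel regression.
    segment_labels
        Per-observation segment ids (aligned with ``variables`` rows).
    pseudotime_table
        A :class:`medtraj.tree.PseudotimeTable` (pseudo-times + memberships).

    Returns long-format tables: ``segment_tests`` (all tests, BH-adjusted),
    ``segment_hits`` (significant with |effect| above threshold) and
    ``trajectory_hits`` (pairs with R^2 above threshold), plus
    ``trajectory_r2`` with every computed R^2.
    """
    seg_rows, seg_assocs = [], []
    for name in variables.columns:
        vals = variables[name].to_numpy()
        try:
            if kinds.get(name, "continuous") == "binary":
                assoc = segment_chi2(segment_labels, vals, variable=name)
            else:
                assoc = segment_anova(segment_labels, vals, variable=name)
        except ValueError:
            continue
        seg_assocs.append(assoc)
        seg_rows.append((name, assoc.test, assoc.statistic, assoc.p_value))
    seg_tests = pd.DataFrame(seg_rows, columns=["variable", "test", "statistic", "p"])
    if len(seg_tests):
        valid = seg_tests["p"].notna()
        adj = np.full(len(seg_tests), np.nan)
        if valid.any():
            adj[valid.to_numpy()] = multipletests(
                seg_tests.loc[valid, "p"], alpha=fdr_level, method="fdr_bh"
            )[1]
        seg_tests["p_adj"] = adj
        for assoc, p_adj in zip(seg_assocs, adj):
            assoc.adjusted_p = None if np.isnan(p_adj) else float(p_adj)

    hits = []
    for assoc in seg_assocs:
        if assoc.adjusted_p is None or assoc.adjusted_p >= fdr_level:
            continue
        if assoc.test == "chi2":
            dev = assoc.effects.abs()
            for seg_id in dev.index:
                m = dev.loc[seg_id].max()
                if m > deviation_threshold:
                    level = dev.loc[seg_id].idxmax()
                    hits.append((assoc.variable, seg_id, "deviation",
                                 float(assoc.effects.loc[seg_id, level]), assoc.adjusted_p))
        else:
            for seg_id, row in assoc.effects.iterrows():
                if abs(row["coef"]) > coef_threshold and (np.isnan(row["p"]) or row["p"] < fdr_level):
                    hits.append((assoc.variable, seg_id, "coef", float(row["coef"]),
                                 assoc.adjusted_p))
    segment_hits = pd.DataFrame(
        hits, columns=["variable", "segment", "effect_kind", "effect", "p_adj"]
    )

    traj_rows = []
    for tr in pseudotime_table.trajectories:
        mask = pseudotime_table.trajectory_members[tr.id]
        pt = pseudotime_table.table["pt"].to_numpy()[mask]
        for name in variables.columns:
            vals = variables[name].to_numpy()[mask]
            kind = "logistic" if kinds.get(name) == "binary" else "kernel"
            try:
                assoc = trajectory_regression(
                    vals, pt, kind=kind, bandwidth=bandwidth,
                    variable=name, trajectory=tr.id,
                )
            except ValueError:
                continue
            traj_rows.append((name, tr.id, kind, assoc.r2))
    trajectory_r2 = pd.DataFrame(traj_rows, columns=["variable", "trajectory", "kind", "r2"])
    trajectory_hits = trajectory_r2[trajectory_r2["r2"] > r2_threshold].reset_index(drop=True)
    return {
        "segment_tests": seg_tests,
        "segment_hits": segment_hits,
        "trajectory_r2": trajectory_r2,
        "trajectory_hits": trajectory_hits,
    }
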
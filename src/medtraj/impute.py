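"""SVD-based multivariate imputation of quantified matrices.

Two low-rank imputers are provided.  ``svd_complete_impute`` builds a rank-k
principal hyperplane from the *complete rows only* and maps each incomplete
row to the nearest point of that hyperplane, nearness being measured over the
row's observed coordinates; the missing coordinates are then read off the
projected point.  ``svd_full_impute`` is the iterative hard-impute variant:
missing cells start at column means and are repeatedly overwritten by a
rank-k reconstruction of the whole (filled) matrix until the imputed values
stabilize.  Both can snap imputed ordinal/binary entries back to admissible
quantified levels and restore mutual exclusivity inside dummy blocks.

The default rank k is the PCA intrinsic-dimension heuristic evaluated on the
complete-row submatrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import QuantifiedMatrix, estimate_intrinsic_dimension_pca

__all__ = ["ImputationResult", "svd_complete_impute", "svd_full_impute"]


@dataclass
class ImputationResult:
    matrix: QuantifiedMatrix
    imputed_cells: list[tuple[int, int]]
    k: int
    iterations: int
    converged: bool
    #: svd_full_impute only: Frobenius error of the rank-k fit on observed
    #: cells, one entry per iteration (non-increasing).
    objective_trace: list[float] = field(default_factory=list)


def _round_discrete(arr: np.ndarray, mask: np.ndarray, qm: QuantifiedMatrix) -> np.ndarray:
    """Snap imputed discrete entries to admissible values, in place.

    Ordinal/binary columns go to the nearest quantified level score; dummy
    blocks of a categorical source get a single 1 at the largest coordinate.
    """
    cols = qm.columns
    colindex = {c: i for i, c in enumerate(cols)}
    in_dummy: set[str] = set()
    for src, members in qm.dummy_groups().items():
        idx = [colindex[c] for c in members]
        in_dummy.update(members)
        rows = np.where(mask[:, idx].any(axis=1))[0]
        for r in rows:
            winner = idx[int(np.argmax(arr[r, idx]))]
            for j in idx:
                if mask[r, j]:
                    arr[r, j] = 1.0 if j == winner else 0.0
    for c in cols:
        if c in in_dummy:
            continue
        if qm.kinds.get(c) in ("ordinal", "binary") and c in qm.maps:
            j = colindex[c]
            levels = np.asarray(qm.maps[c].scores, dtype=float)
            rows = np.where(mask[:, j])[0]
            if len(rows):
                arr[rows, j] = levels[np.argmin(np.abs(arr[rows, j][:, None] - levels[None, :]), axis=1)]
    return arr


def _finalize(qm: QuantifiedMatrix, arr: np.ndarray, mask: np.ndarray,
              k: int, iterations: int, converged: bool, round_discrete: bool,
              objective_trace: list[float] | None = None) -> ImputationResult:
    if round_discrete:
        arr = _round_discrete(arr, mask, qm)
    out = qm.copy()
    out.data = pd.DataFrame(arr, index=qm.data.index, columns=qm.columns)
    cells = [(int(i), int(j)) for i, j in zip(*np.where(mask))]
    return ImputationResult(matrix=out, imputed_cells=cells, k=k,
                            iterations=iterations, converged=converged,
                            objective_trace=objective_trace or [])


def svd_complete_impute(
    qm: QuantifiedMatrix,
    k: int | None = None,
    round_discrete: bool = False,
) -> ImputationResult:
    """Impute via the principal hyperplane of the complete rows.

    The top-k principal components of the complete-row submatrix (centered on
    complete-row column means) span an affine hyperplane; each incomplete row
    is projected onto it using only its observed coordinates and the missing
    coordinates are read from the projection.  Observed cells are never
    modified.  Requires at least ``k + 1`` complete rows.
    """
    arr = qm.data.to_numpy(dtype=float).copy()
    mask = np.isnan(arr)
    if not mask.any():
        return _finalize(qm, arr, mask, k or 0, 0, True, round_discrete)
    complete = ~mask.any(axis=1)
    sub = arr[complete]
    if k is None:
        if sub.shape[0] < 2:
            raise ValueError(
                "too few complete rows to choose k automatically; "
                "consider svd_full_impute"
            )
        k = max(1, estimate_intrinsic_dimension_pca(sub))
    if sub.shape[0] < k + 1:
        raise ValueError(
            f"only {sub.shape[0]} complete rows for rank k={k}; "
            "consider svd_full_impute"
        )
    mean = sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub - mean, full_matrices=False)
    basis = vt[:k]  # (k, p)
    for i in np.where(mask.any(axis=1))[0]:
        obs = ~mask[i]
        a, *_ = np.linalg.lstsq(basis[:, obs].T, arr[i, obs] - mean[obs], rcond=None)
        recon = mean + a @ basis
        arr[i, mask[i]] = recon[mask[i]]
    return _finalize(qm, arr, mask, k, 1, True, round_discrete)


def svd_full_impute(
    qm: QuantifiedMatrix,
    k: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    round_discrete: bool = False,
) -> ImputationResult:
    """Iterative rank-k (hard-impute) completion using all rows.

    Missing cells are initialized at observed-cell column means; then the
    filled matrix is repeatedly replaced on its missing cells by its own
    rank-k reconstruction (SVD of the matrix centered on the fixed observed
    column means) until the largest absolute change over missing cells drops
    below ``tol`` or ``max_iter`` is reached.  Observed cells are never
    modified.  Every column needs at least one observed value.
    """
    arr = qm.data.to_numpy(dtype=float).copy()
    mask = np.isnan(arr)
    if not mask.any():
        return _finalize(qm, arr, mask, k or 0, 0, True, round_discrete)
    if mask.all(axis=0).any():
        raise ValueError("every column must have at least one observed value")
    col_means = np.nanmean(arr, axis=0)
    if k is None:
        complete = ~mask.any(axis=1)
        k = max(1, estimate_intrinsic_dimension_pca(arr[complete])) if complete.sum() >= 2 else 1
    filled = arr.copy()
    filled[mask] = np.take(col_means, np.where(mask)[1])
    converged = False
    it = 0
    objective: list[float] = []
    for it in range(1, max_iter + 1):
        # recenter on the current filled matrix so an affine rank-k structure
        # can be recovered exactly (mean + SVD is the optimal such fit)
        col_means = filled.mean(axis=0)
        centered = filled - col_means
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k] + col_means
        objective.append(float(np.sum((recon[~mask] - arr[~mask]) ** 2)))
        delta = np.max(np.abs(recon[mask] - filled[mask]))
        filled[mask] = recon[mask]
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("svd_full_impute did not converge; returning last iterate")
    return _finalize(qm, filled, mask, k, it, converged, round_discrete, objective)
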
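"""Shared statistical machinery: Bray-Curtis distances, principal
coordinates analysis, one-factor PERMANOVA, the Mantel test and
Benjamini-Hochberg adjustment.

Permutation p-values use the +1 correction,
``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``, so a permutation test
never reports exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    values: np.ndarray  # n x n, symmetric, zero diagonal
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise InputError("ids do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise InputError("negative distances")
        self.values = v


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between the samples (columns) of an
    abundance matrix: ``d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)``.

    A pair of all-zero samples has an undefined dissimilarity; it is
    reported as 0 with a warning.
    """
    frame = matrix.values if hasattr(matrix, "values") and hasattr(matrix, "state") else matrix
    X = np.asarray(frame, dtype=float)
    if (X < 0).any():
        raise InputError("Bray-Curtis requires nonnegative abundances")
    ids = list(frame.columns) if isinstance(frame, pd.DataFrame) else [str(i) for i in range(X.shape[1])]
    n = X.shape[1]
    D = np.zeros((n, n))
    warned = False
    for i in range(n):
        for j in range(i + 1, n):
            denom = (X[:, i] + X[:, j]).sum()
            if denom == 0:
                if not warned:
                    warnings.warn("all-zero sample pair: Bray-Curtis set to 0")
                    warned = True
                d = 0.0
            else:
                d = np.abs(X[:, i] - X[:, j]).sum() / denom
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids)


def pcoa(dist: DistanceMatrix, eps: float = 1e-9) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (metric) scaling of a distance matrix.

    Double-centers ``-D^2/2``, eigendecomposes, and returns coordinates
    on the axes with positive eigenvalues (ordered by decreasing
    eigenvalue) together with the full eigenvalue spectrum; axes with
    negative eigenvalues are reported in the spectrum but dropped from
    the coordinates.
    """
    n = len(dist.ids)
    if n < 3:
        raise InputError("PCoA needs at least 3 samples")
    D2 = dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eps
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    frame = pd.DataFrame(
        coords, index=dist.ids, columns=[f"PCo{i + 1}" for i in range(int(keep.sum()))]
    )
    return frame, eigvals


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = D2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """One-factor PERMANOVA on a distance matrix (adonis formulation).

    pseudo-F = (SS_among / (k-1)) / (SS_within / (n-k)); the p-value is
    the fraction of label permutations with F at least as large as
    observed, with the +1 correction.  R^2 = SS_among / SS_total.
    """
    labels = np.asarray(groups)
    n = len(dist.ids)
    if labels.shape[0] != n:
        raise InputError("group labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InputError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise InputError("every group needs at least 2 samples")
    k = len(uniq)
    D2 = dist.values**2
    ss_total, ss_within = _permanova_ss(D2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    f_obs = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf
    rng = np.random.default_rng(seed)
    if not np.isfinite(f_obs):
        # perfect separation: no permutation statistic can exceed the
        # infinite observed F, so the +1-corrected minimum is reported
        p = 1.0 / (1 + n_perm)
    else:
        count_ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            _, ssw = _permanova_ss(D2, perm)
            ssa = ss_total - ssw
            f = (ssa / df_among) / (ssw / df_within) if ssw > 0 else np.inf
            if f >= f_obs:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_perm)
    return {
        "pseudo_F": float(f_obs),
        "R2": float(ss_among / ss_total) if ss_total > 0 else np.nan,
        "p_value": float(p),
        "n_perm": n_perm,
    }


def mantel(
    dist1: DistanceMatrix,
    dist2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Mantel test: Pearson correlation of the lower triangles of two
    distance matrices, permutation p-value (one-sided, r >= observed)."""
    if dist1.ids != dist2.ids:
        raise InputError("Mantel requires matching sample sets in the same order")
    n = len(dist1.ids)
    iu = np.triu_indices(n, k=1)
    x, y = dist1.values[iu], dist2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant distance matrix: Mantel r undefined")
        return {"r": np.nan, "p_value": np.nan, "n_perm": n_perm}
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = dist2.values[np.ix_(perm, perm)][iu]
        if float(np.corrcoef(x, yp)[0, 1]) >= r_obs:
            count_ge += 1
    return {"r": r_obs, "p_value": (1 + count_ge) / (1 + n_perm), "n_perm": n_perm}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i}(p_(j) * n / j)`` on the sorted p-values,
    capped at 1, returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
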
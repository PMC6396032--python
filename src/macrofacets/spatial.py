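"""Spatial eigenvectors (dbMEM / PCNM) and Moran's I statistics.

The dbMEM basis is built by principal coordinates analysis of a truncated
Euclidean distance matrix: distances beyond the longest edge of the
minimum spanning tree (the threshold ``t``) are replaced by ``4 t``.
Eigenvectors with positive eigenvalues form the spatial predictors;
low-order columns describe broad-scale, high-order columns fine-scale
spatial patterns (their Moran's I decreases with column order on regular
layouts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .io import warn_once


def euclidean_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise planar Euclidean distances between site centroids."""
    if len(coords) < 3:
        raise ValueError("need at least 3 sites")
    pts = coords[["x", "y"]].to_numpy(dtype=float)
    d = squareform(pdist(pts))
    off = d[np.triu_indices_from(d, 1)]
    if (off == 0).any():
        raise ValueError("duplicate coordinates: zero off-diagonal distance")
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


def mst_threshold(dist: pd.DataFrame | np.ndarray) -> float:
    """Longest edge of the minimum spanning tree of the complete site graph."""
    d = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist)
    tree = minimum_spanning_tree(d)
    return float(tree.data.max())


def truncate_distances(
    dist: pd.DataFrame, t: float, multiplier: float = 4.0
) -> pd.DataFrame:
    """Replace distances beyond ``t`` with ``multiplier * t``; keep diagonal 0."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    d = dist.to_numpy(dtype=float).copy()
    d[d > t] = multiplier * t
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=dist.index, columns=dist.columns)


class DbMEM(BaseEstimator, TransformerMixin):
    """Distance-based Moran's eigenvector maps of a set of site centroids.

    A transformer in the scikit-learn sense: ``fit`` takes the n x 2 array
    (or DataFrame with columns x, y) of planar coordinates and computes the
    eigenvectors; ``transform`` returns the basis for the fitted sites.
    The eigenvectors are only defined for the sites they were fitted on.

    Parameters
    ----------
    truncation_multiplier : float, default 4.0
        Replacement factor for beyond-threshold distances.
    eig_tol : float, default 1e-9
        Eigenvalues below ``eig_tol`` times the largest are discarded.

    Attributes
    ----------
    basis_ : DataFrame, sites x eigenvectors (dbMEM1, dbMEM2, ...),
        each column centered and scaled to norm sqrt(eigenvalue),
        decreasing eigenvalue order.
    eigenvalues_ : ndarray of the retained (positive) eigenvalues.
    threshold_ : float, the minimum-spanning-tree truncation distance.
    """

    def __init__(self, truncation_multiplier: float = 4.0, eig_tol: float = 1e-9):
        self.truncation_multiplier = truncation_multiplier
        self.eig_tol = eig_tol

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            coords = X[["x", "y"]] if {"x", "y"}.issubset(X.columns) else X
            index = X.index
            pts = coords.to_numpy(dtype=float)
        else:
            pts = np.asarray(X, dtype=float)
            index = pd.RangeIndex(len(pts))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("coordinates must be an n x 2 array")
        dist = pd.DataFrame(squareform(pdist(pts)), index=index, columns=index)
        off = dist.to_numpy()[np.triu_indices(len(pts), 1)]
        if (off == 0).any():
            raise ValueError("duplicate coordinates")
        t = mst_threshold(dist)
        trunc = truncate_distances(dist, t, self.truncation_multiplier).to_numpy()
        n = len(pts)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (trunc**2) @ j
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        keep = evals > self.eig_tol * evals[0]
        if not keep.any():
            raise ValueError("degenerate geometry: no positive eigenvalue")
        vecs = evecs[:, keep] * np.sqrt(evals[keep])
        cols = [f"dbMEM{i + 1}" for i in range(vecs.shape[1])]
        self.basis_ = pd.DataFrame(vecs, index=index, columns=cols)
        self.eigenvalues_ = evals[keep]
        self.threshold_ = t
        self.n_features_in_ = 2
        return self

    def transform(self, X=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "basis_")
        return self.basis_


def dbmem_basis(
    coords: pd.DataFrame, truncation_multiplier: float = 4.0
) -> DbMEM:
    """Fit and return a :class:`DbMEM` on the given site coordinates."""
    return DbMEM(truncation_multiplier=truncation_multiplier).fit(coords)


# ---------------------------------------------------------------- Moran's I

@dataclass
class MoranResult:
    I: float
    expected: float
    p: float
    n: int
    test: str


def _moran_stat(z: np.ndarray, w: np.ndarray, w_sum: float) -> float:
    return len(z) / w_sum * float(z @ w @ z) / float(z @ z)


def morans_i(
    values,
    weights,
    test: str = "permutation",
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Moran's I with a two-sided test against E[I] = -1/(n-1).

    ``test`` is ``permutation`` (default; random relabeling of values over
    sites, p = (exceedances + 1)/(n_perm + 1)) or ``normal`` (Gaussian
    approximation under randomization).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("values have zero variance")
    if np.any(np.diag(w) != 0):
        raise ValueError("weight matrix must have zero diagonal")
    w_sum = w.sum()
    if w_sum == 0:
        raise ValueError("weight matrix sums to zero")
    z = x - x.mean()
    i_obs = _moran_stat(z, w, w_sum)
    e_i = -1.0 / (n - 1)
    if test == "permutation":
        rng = np.random.default_rng(rng)
        perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)  # n_perm x n
        num = np.einsum("pi,ij,pj->p", perms, w, perms)
        i_perm = n / w_sum * num / float(z @ z)
        exceed = np.sum(np.abs(i_perm - e_i) >= abs(i_obs - e_i) - 1e-12)
        p = (exceed + 1) / (n_perm + 1)
    elif test == "normal":
        s0 = w_sum
        s1 = 0.5 * np.sum((w + w.T) ** 2)
        s2 = np.sum((w.sum(axis=0) + w.sum(axis=1)) ** 2)
        b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
        var = (
            n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
            - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        if var <= 0:
            p = np.nan
        else:
            zscore = (i_obs - e_i) / np.sqrt(var)
            p = 2 * norm.sf(abs(zscore))
    else:
        raise ValueError(f"unknown test {test!r}")
    return MoranResult(I=i_obs, expected=e_i, p=float(p), n=n, test=test)


def correlogram(
    values,
    coords: pd.DataFrame,
    n_classes: int = 10,
    alpha: float = 0.05,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    adjustment: str = "progressive",
) -> pd.DataFrame:
    """Moran's I correlogram over equal-width distance classes.

    Classes partition (0, d_max]; pair weights are 1 when the pair's
    distance falls in the class.  Significance per class uses the
    permutation test; the progressive Bonferroni correction tests class k
    at ``alpha / k``.  Empty classes get NaN with a warning.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    x = np.asarray(values, dtype=float)
    dist = euclidean_distance_matrix(coords).to_numpy()
    d_max = dist.max()
    edges = np.linspace(0.0, d_max, n_classes + 1)
    rng = np.random.default_rng(rng)
    rows = []
    warned = False
    for k in range(n_classes):
        lo, hi = edges[k], edges[k + 1]
        w = ((dist > lo) & (dist <= hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        n_pairs = int(w.sum() // 2)
        if n_pairs == 0:
            if not warned:
                warn_once(f"empty distance class ({lo:.3g}, {hi:.3g}]")
                warned = True
            rows.append((k + 1, lo, hi, 0, np.nan, np.nan, False))
            continue
        res = morans_i(x, w, test="permutation", n_perm=n_perm, rng=rng)
        thr = alpha / (k + 1) if adjustment == "progressive" else alpha
        rows.append((k + 1, lo, hi, n_pairs, res.I, res.p, res.p <= thr))
    return pd.DataFrame(
        rows,
        columns=["class", "d_lo", "d_hi", "n_pairs", "I", "p", "significant"],
    )
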
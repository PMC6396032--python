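"""Spatial congruence of top-percentile site sets and index correlations.

Congruence between two diversity indices is the percentage overlap of
their top-percentile site sets (e.g. the 10% of sites with the highest
values of each).  A randomization null draws two independent uniform
k-subsets of the sites; the overlap then follows the hypergeometric
distribution with mean k^2 / n, which is reported alongside the Monte
Carlo null as an analytic cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def top_set(values: pd.Series, percentile: float) -> pd.Index:
    """The ``floor(percentile * n)`` (at least 1) sites with largest values.

    Sites with undefined (NaN) values are excluded first.  Boundary ties
    are broken deterministically by the original site-label order.
    """
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    v = values.dropna()
    n = len(v)
    if n == 0:
        raise ValueError("all values undefined")
    k = max(1, int(np.floor(percentile * n)))
    order = np.lexsort((np.arange(n), -v.to_numpy()))  # value desc, stable
    return v.index[order[:k]]


@dataclass
class CongruenceNull:
    null_mean: float
    p: float
    expected: float     # hypergeometric mean k^2 / n
    n_iter: int


def congruence_null(
    n_sites: int,
    k: int,
    observed: int,
    n_iter: int = 999,
    rng: np.random.Generator | int | None = None,
) -> CongruenceNull:
    """Randomization null for the overlap of two top-k site sets.

    Each iteration draws two independent uniform k-subsets of the n sites
    and records their overlap; p = (count(null >= observed) + 1) /
    (n_iter + 1).
    """
    if k > n_sites:
        raise ValueError("k cannot exceed the number of sites")
    rng = np.random.default_rng(rng)
    base = np.tile(np.arange(n_sites), (n_iter, 1))
    seta = rng.permuted(base, axis=1)[:, :k]
    setb = rng.permuted(base, axis=1)[:, :k]
    mask = np.zeros((n_iter, n_sites), dtype=bool)
    np.put_along_axis(mask, seta, True, axis=1)
    overlaps = np.take_along_axis(mask, setb, axis=1).sum(axis=1)
    p = (np.sum(overlaps >= observed) + 1) / (n_iter + 1)
    return CongruenceNull(
        null_mean=float(overlaps.mean()),
        p=float(p),
        expected=k * k / n_sites,
        n_iter=n_iter,
    )


def pairwise_congruence(
    profile: pd.DataFrame,
    indices: list[str] | None = None,
    step: float = 0.10,
    n_iter: int = 999,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Overlap percentage for every index pair at successive percentile bands.

    For each unordered pair of index columns and each level in
    ``{step, 2*step, ..., 1}``, the overlap of the two top-level site sets
    is computed on the sites where both indices are defined, with the
    randomization null and its analytic expectation.
    """
    rng = np.random.default_rng(rng)
    if indices is None:
        indices = [c for c in profile.columns if c != "S"]
    levels = np.arange(step, 1.0 + 1e-9, step)
    rows = []
    for ia, ib in itertools.combinations(indices, 2):
        both = profile[[ia, ib]].dropna()
        n = len(both)
        if n < 2:
            continue
        for lev in levels:
            sa = top_set(both[ia], lev)
            sb = top_set(both[ib], lev)
            k = len(sa)
            overlap = len(sa.intersection(sb))
            null = congruence_null(n, k, overlap, n_iter=n_iter, rng=rng)
            rows.append(
                (
                    ia, ib, round(float(lev), 10), k, overlap,
                    100.0 * overlap / k, null.null_mean, null.expected, null.p,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "index_a", "index_b", "level", "k", "overlap",
            "overlap_pct", "null_mean", "null_expected", "p",
        ],
    )


def correlation_matrix(
    profile: pd.DataFrame, indices: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between diversity indices.

    Returns the r matrix and the two-sided t-test p matrix.  Pairs with
    fewer than 3 common defined sites or a zero-variance index get NaN.
    """
    if indices is None:
        indices = [c for c in profile.columns if c != "S"]
    m = len(indices)
    r = pd.DataFrame(np.eye(m), index=indices, columns=indices)
    p = pd.DataFrame(np.zeros((m, m)), index=indices, columns=indices)
    for ia, ib in itertools.combinations(indices, 2):
        both = profile[[ia, ib]].dropna()
        if len(both) < 3 or both[ia].std() == 0 or both[ib].std() == 0:
            rv = pv = np.nan
        else:
            rv, pv = stats.pearsonr(both[ia], both[ib])
        r.loc[ia, ib] = r.loc[ib, ia] = rv
        p.loc[ia, ib] = p.loc[ib, ia] = pv
    np.fill_diagonal(p.values, 0.0)
    return r, p
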
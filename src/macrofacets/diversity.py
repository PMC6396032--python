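"""Per-site diversity indices from incidence, trait and taxonomy tables.

Six indices are computed for each site (community):

* TRic — taxonomic richness, the species count;
* TDis — average taxonomic distinctness (Delta+ for presence/absence): the
  mean rank-hierarchy distance over all unordered pairs of species present;
* FRic — functional richness, the convex-hull volume of the community in a
  trait-space ordination;
* FEve — functional evenness, regularity of minimum-spanning-tree branch
  lengths in trait space;
* FDiv — functional divergence, spread of species relative to the gravity
  center of the hull vertices;
* FDis — functional dispersion, mean distance to the community centroid.

Trait space is built by principal coordinates analysis of a Gower
dissimilarity over four categorical traits and one quantitative trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .io import TAXONOMY_RANKS, TRAIT_LEVELS, warn_once

INDEX_NAMES = ["TRic", "TDis", "FRic", "FEve", "FDiv", "FDis"]


# ---------------------------------------------------------------- taxonomy

def taxonomic_distance_matrix(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Rank-hierarchy distance between species with equal branch lengths.

    The distance between two distinct species is the height of their lowest
    shared rank, counting equal unit steps species -> genus -> family ->
    order -> subclass -> class -> phylum -> root (so species in different
    phyla sit at height 7).  The matrix is rescaled so the maximum realized
    off-diagonal distance is 100 — the convention of the standard
    distinctness tooling, which makes TDis a 0-100 scale.
    """
    ranks = [r for r in TAXONOMY_RANKS if r in taxonomy.columns]
    if len(ranks) != len(TAXONOMY_RANKS):
        raise ValueError(f"taxonomy must contain ranks {TAXONOMY_RANKS}")
    n = len(taxonomy)
    height = np.full((n, n), float(len(ranks) + 1))
    # overwrite from phylum (height 6) down to genus (height 1): nesting
    # consistency means equality at a low rank implies equality above it,
    # so the last write is the lowest shared rank.
    for i in range(len(ranks) - 1, -1, -1):
        codes = pd.factorize(taxonomy[ranks[i]])[0]
        eq = codes[:, None] == codes[None, :]
        height[eq] = i + 1
    np.fill_diagonal(height, 0.0)
    hmax = height.max()
    if hmax == 0:
        raise ValueError("need at least two distinct species")
    d = height * (100.0 / hmax)
    return pd.DataFrame(d, index=taxonomy.index, columns=taxonomy.index)


def taxonomic_richness(occurrence: pd.DataFrame) -> pd.Series:
    """Number of species present per site."""
    return occurrence.sum(axis=1).rename("TRic")


def taxonomic_distinctness(
    occurrence: pd.DataFrame, tdm: pd.DataFrame
) -> pd.Series:
    """Average taxonomic distinctness (Delta+) per site; NaN for S < 2."""
    d = tdm.loc[occurrence.columns, occurrence.columns].to_numpy()
    inc = occurrence.to_numpy(dtype=float)
    s = inc.sum(axis=1)
    pair_sums = np.einsum("ij,jk,ik->i", inc, d, inc) / 2.0
    n_pairs = s * (s - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n_pairs > 0, pair_sums / n_pairs, np.nan)
    return pd.Series(vals, index=occurrence.index, name="TDis")


# ------------------------------------------------------------- trait space

def gower_distance(traits: pd.DataFrame, weight_transform: str = "none") -> pd.DataFrame:
    """Gower dissimilarity over the 4 categorical traits and adult weight.

    Each pair's dissimilarity is the mean over the five variables of a
    simple mismatch (0/1) for the categoricals and of the range-normalized
    absolute difference for adult weight (optionally log-transformed
    first).  Values lie in [0, 1].  A zero weight range contributes 0 with
    a warning.
    """
    cats = list(TRAIT_LEVELS)
    n = len(traits)
    total = np.zeros((n, n))
    for col in cats:
        codes = pd.factorize(traits[col])[0]
        total += (codes[:, None] != codes[None, :]).astype(float)
    w = traits["adult_weight"].to_numpy(dtype=float)
    if weight_transform == "log":
        w = np.log(w)
    elif weight_transform != "none":
        raise ValueError(f"unknown weight_transform {weight_transform!r}")
    rng = w.max() - w.min()
    if rng == 0:
        warn_once("adult_weight has zero range; it contributes 0 to Gower distance")
    else:
        total += np.abs(w[:, None] - w[None, :]) / rng
    total /= 5.0
    np.fill_diagonal(total, 0.0)
    return pd.DataFrame(total, index=traits.index, columns=traits.index)


@dataclass
class TraitSpace:
    """Species coordinates from a PCoA of the (corrected) Gower matrix."""

    coords: pd.DataFrame        # species x axes, decreasing eigenvalue order
    eigenvalues: np.ndarray
    correction: str
    gower: pd.DataFrame

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]


def _cailliez_constant(d: np.ndarray) -> float:
    # smallest additive constant making D + c (off-diagonal) Euclidean
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * j @ (d**2) @ j
    d2 = -0.5 * j @ d @ j
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(max(ev.real.max(), 0.0))


def pcoa(d: np.ndarray, eig_tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Gower-centers -D^2/2, eigendecomposes, and returns coordinates
    ``U * sqrt(lambda)`` for eigenvalues above ``eig_tol`` times the
    largest, in decreasing order, along with all eigenvalues (descending).
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_tol * max(evals[0], np.finfo(float).tiny)
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return coords, evals


def build_trait_space(
    gower: pd.DataFrame, correction: str = "sqrt", neg_tol: float = 1e-6
) -> TraitSpace:
    """PCoA of the Gower matrix with negative-eigenvalue correction.

    ``sqrt`` takes the element-wise square root of dissimilarities before
    the PCoA (the default of the standard functional-diversity tooling);
    ``cailliez`` adds the smallest constant making the matrix Euclidean;
    ``none`` ordinates the raw matrix and errors if sizeable negative
    eigenvalues remain.
    """
    d = gower.to_numpy(dtype=float).copy()
    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction == "cailliez":
        c = _cailliez_constant(d)
        d = d + c
        np.fill_diagonal(d, 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    coords, evals = pcoa(d)
    if evals[0] <= 0:
        raise ValueError("dissimilarity matrix has no positive eigenvalue")
    if -evals.min() > neg_tol * evals[0]:
        raise ValueError(
            f"correction {correction!r} leaves negative eigenvalues "
            f"(min {evals.min():.3g} vs max {evals[0]:.3g}); "
            "try correction='cailliez'"
        )
    axes = [f"axis{i + 1}" for i in range(coords.shape[1])]
    return TraitSpace(
        coords=pd.DataFrame(coords, index=gower.index, columns=axes),
        eigenvalues=evals,
        correction=correction,
        gower=gower,
    )


# ------------------------------------------------------ functional indices

def _site_points(
    space: TraitSpace, occurrence: pd.DataFrame, n_axes: int | None
) -> tuple[np.ndarray, np.ndarray]:
    pts = space.coords.loc[occurrence.columns].to_numpy()
    if n_axes is not None:
        pts = pts[:, :n_axes]
    return occurrence.to_numpy(dtype=bool), pts


def functional_richness(
    space: TraitSpace, occurrence: pd.DataFrame, n_axes: int
) -> pd.Series:
    """Convex-hull volume of each community in the first ``n_axes`` axes.

    Undefined (NaN) when S <= n_axes; degenerate point sets (collinear /
    coplanar) yield volume 0 with a warning.
    """
    if n_axes < 2:
        raise ValueError("n_axes must be >= 2 for a hull volume")
    inc, pts = _site_points(space, occurrence, n_axes)
    out = np.full(len(occurrence), np.nan)
    warned = False
    for i, row in enumerate(inc):
        p = pts[row]
        if len(p) <= n_axes:
            continue
        try:
            out[i] = ConvexHull(p).volume
        except QhullError:
            if not warned:
                warn_once("degenerate point set(s): convex-hull volume set to 0")
                warned = True
            out[i] = 0.0
    return pd.Series(out, index=occurrence.index, name="FRic")


def _mst_branches(d: np.ndarray) -> np.ndarray:
    tree = minimum_spanning_tree(d).tocoo()
    return tree.data


def functional_evenness(
    space: TraitSpace, occurrence: pd.DataFrame, n_axes: int | None = None
) -> pd.Series:
    """Regularity of minimum-spanning-tree branch lengths; NaN for S < 3.

    With equal (presence/absence) weights, the partial evenness of branch
    ``l`` is its length divided by the total tree length, compared against
    the even share 1/(S-1):

        FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))
    """
    inc, pts = _site_points(space, occurrence, n_axes)
    out = np.full(len(occurrence), np.nan)
    for i, row in enumerate(inc):
        s = int(row.sum())
        if s < 3:
            continue
        d = squareform(pdist(pts[row]))
        branches = _mst_branches(d)
        tot = branches.sum()
        if tot == 0:
            out[i] = np.nan  # all species functionally identical
            continue
        pew = branches / tot
        thr = 1.0 / (s - 1)
        out[i] = (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)
    return pd.Series(out, index=occurrence.index, name="FEve")


def functional_divergence(
    space: TraitSpace, occurrence: pd.DataFrame, n_axes: int | None = None
) -> pd.Series:
    """Spread of species relative to the hull vertices' gravity center.

    G is the centroid of the convex-hull vertex species; with equal weights
    w = 1/S, dG the distances of all present species to G, d-bar their
    mean, Dd = sum w (dG - d-bar) and D|d| = sum w |dG - d-bar|:

        FDiv = (Dd + d-bar) / (D|d| + d-bar)

    NaN for S < 3 or when every species sits exactly at G.  For degenerate
    (e.g. collinear) communities where the hull has no volume, all present
    species are treated as hull vertices.
    """
    inc, pts = _site_points(space, occurrence, n_axes)
    out = np.full(len(occurrence), np.nan)
    for i, row in enumerate(inc):
        s = int(row.sum())
        if s < 3:
            continue
        p = pts[row]
        try:
            verts = ConvexHull(p).vertices
            g = p[verts].mean(axis=0)
        except QhullError:
            g = p.mean(axis=0)
        dg = np.linalg.norm(p - g, axis=1)
        dbar = dg.mean()
        if dbar == 0:
            continue
        dev = dg - dbar
        dd = dev.mean()
        dabs = np.abs(dev).mean()
        out[i] = (dd + dbar) / (dabs + dbar)
    return pd.Series(out, index=occurrence.index, name="FDiv")


def functional_dispersion(
    space: TraitSpace, occurrence: pd.DataFrame, n_axes: int | None = None
) -> pd.Series:
    """Mean distance of present species to their (equal-weight) centroid."""
    inc, pts = _site_points(space, occurrence, n_axes)
    out = np.full(len(occurrence), np.nan)
    for i, row in enumerate(inc):
        s = int(row.sum())
        if s == 0:
            continue
        p = pts[row]
        c = p.mean(axis=0)
        out[i] = float(np.linalg.norm(p - c, axis=1).mean())
    return pd.Series(out, index=occurrence.index, name="FDis")


# ---------------------------------------------------------------- assembly

def default_n_axes(occurrence: pd.DataFrame, cap: int = 3) -> int:
    """Hull-axis policy: min(cap, smallest site richness - 1), at least 2."""
    s_min = int(occurrence.sum(axis=1).min())
    return max(2, min(cap, s_min - 1))


def diversity_profile(dataset, config=None) -> pd.DataFrame:
    """All six indices per site, with NaN where an index is undefined.

    Returns a DataFrame indexed by site with columns S, TRic, TDis, FRic,
    FEve, FDiv, FDis.  ``dataset`` is an :class:`~macrofacets.io.Dataset`;
    ``config`` an optional :class:`~macrofacets.config.AnalysisConfig`
    controlling the PCoA correction and hull-axis count.
    """
    from .config import AnalysisConfig

    config = config or AnalysisConfig()
    occ = dataset.occurrence
    tdm = taxonomic_distance_matrix(dataset.taxonomy)
    gow = gower_distance(dataset.traits)
    space = build_trait_space(gow, correction=config.pcoa_correction)
    n_axes = (
        config.n_fric_axes
        if config.n_fric_axes is not None
        else default_n_axes(occ)
    )
    n_axes = min(n_axes, space.n_axes)
    prof = pd.DataFrame(
        {
            "S": occ.sum(axis=1),
            "TRic": taxonomic_richness(occ),
            "TDis": taxonomic_distinctness(occ, tdm),
            "FRic": functional_richness(space, occ, n_axes),
            "FEve": functional_evenness(space, occ, n_axes),
            "FDiv": functional_divergence(space, occ, n_axes),
            "FDis": functional_dispersion(space, occ, n_axes),
        }
    )
    prof.attrs["n_axes"] = n_axes
    prof.attrs["mean_richness_share"] = float(
        (prof["TRic"] / occ.shape[1]).mean()
    )
    return prof
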
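"""Independent, naively coded reference implementations used as oracles.

Everything here is written directly from the defining formulas with plain
loops, deliberately sharing no code with the package.
"""

import itertools

import numpy as np


def gower_pair(row_a, row_b, weight_range):
    """Mean over 4 categorical mismatches + range-normalized weight diff."""
    total = 0.0
    for k in range(4):
        total += 0.0 if row_a[k] == row_b[k] else 1.0
    if weight_range > 0:
        total += abs(row_a[4] - row_b[4]) / weight_range
    return total / 5.0


def tdis_site(present_idx, dist):
    pairs = list(itertools.combinations(present_idx, 2))
    if not pairs:
        return np.nan
    return float(np.mean([dist[i, j] for i, j in pairs]))


def convex_hull_2d(points):
    """Monotone-chain hull; returns vertex indices in CCW order."""
    pts = sorted(range(len(points)), key=lambda i: (points[i][0], points[i][1]))

    def cross(o, a, b):
        return (points[a][0] - points[o][0]) * (points[b][1] - points[o][1]) - (
            points[a][1] - points[o][1]
        ) * (points[b][0] - points[o][0])

    lower = []
    for i in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], i) <= 0:
            lower.pop()
        lower.append(i)
    upper = []
    for i in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], i) <= 0:
            upper.pop()
        upper.append(i)
    return lower[:-1] + upper[:-1]


def shoelace_area(points):
    hull = convex_hull_2d(points)
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = points[hull[i]]
        x2, y2 = points[hull[(i + 1) % len(hull)]]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def prim_mst_edges(dist):
    """Naive Prim; returns the list of MST edge lengths."""
    n = dist.shape[0]
    in_tree = {0}
    edges = []
    while len(in_tree) < n:
        best = (np.inf, None)
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and dist[i, j] < best[0]:
                    best = (dist[i, j], j)
        edges.append(best[0])
        in_tree.add(best[1])
    return edges


def feve_direct(points):
    """Direct evaluation of the evenness formula on one community."""
    s = len(points)
    dist = np.zeros((s, s))
    for i in range(s):
        for j in range(s):
            dist[i, j] = np.linalg.norm(np.asarray(points[i]) - np.asarray(points[j]))
    branches = prim_mst_edges(dist)
    total = sum(branches)
    if total == 0:
        return np.nan
    pew = [b / total for b in branches]
    thr = 1.0 / (s - 1)
    return (sum(min(p, thr) for p in pew) - thr) / (1.0 - thr)


def fdiv_direct(points):
    """Step-by-step divergence: hull gravity center, deviations, ratio."""
    pts = np.asarray(points, dtype=float)
    hull = convex_hull_2d(points)
    if len(hull) < 3:
        g = pts.mean(axis=0)
    else:
        g = pts[hull].mean(axis=0)
    dg = np.array([np.linalg.norm(p - g) for p in pts])
    dbar = dg.mean()
    if dbar == 0:
        return np.nan
    dev = dg - dbar
    return (dev.mean() + dbar) / (np.abs(dev).mean() + dbar)


def fdis_direct(points):
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    return float(np.mean([np.linalg.norm(p - c) for p in pts]))


def moran_double_sum(values, weights):
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return n / w.sum() * num / np.sum(z**2)


def ols_normal_equations(y, x):
    """Intercept-included OLS via the normal equations; returns (beta, r2)."""
    design = np.c_[np.ones(len(y)), x]
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ beta
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    return beta, 1.0 - np.sum(resid**2) / ss_tot
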
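"""Linear modeling of per-site diversity on environmental and spatial
predictors.

Because each response is a single diversity index, redundancy analysis
reduces exactly to multiple linear regression, so every stage here is OLS
with an intercept: permutation tests of R-squared, Blanchet-style forward
selection with the double stopping rule, variance inflation factors, and
variation partitioning on the adjusted R-squared (Ezekiel) scale into the
pure-environment fraction a = [E|S], the spatially structured environment
fraction b = [E n S], the pure-space fraction c = [S|E] and the residual d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _orthobasis(xc: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column span of a centered matrix."""
    if xc.shape[1] == 0:
        return np.zeros((xc.shape[0], 0))
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    keep = s > tol * max(s[0], np.finfo(float).tiny)
    return u[:, keep]


def _r2(y: np.ndarray, xc: np.ndarray) -> float:
    """R^2 of an intercept-included OLS of y on the columns of X."""
    z = y - y.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("response has zero variance")
    q = _orthobasis(xc - xc.mean(axis=0))
    proj = q.T @ z
    return float(proj @ proj) / ss


# ------------------------------------------------------------------- OLS fit

@dataclass
class ModelFit:
    response: str
    coefficients: pd.Series     # signed, selection/ column order (no intercept)
    intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    residuals: pd.Series
    fitted: pd.Series


def fit_linear(y, X, response_name: str = "y") -> ModelFit:
    """Ordinary least squares with intercept via statsmodels.

    Raises on rank deficiency, listing a collinear subset of columns.
    """
    Xf = _as_frame(X)
    yv = np.asarray(y, dtype=float)
    n, p = Xf.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    design = sm.add_constant(Xf.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < p + 1:
        xc = Xf.to_numpy() - Xf.to_numpy().mean(axis=0)
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        dead = np.abs(vt[-1]) > 1e-8
        cols = list(Xf.columns[dead])
        raise ValueError(f"rank-deficient predictors; collinear set: {cols}")
    res = sm.OLS(yv, design).fit()
    index = Xf.index if isinstance(y, pd.Series) is False else y.index
    return ModelFit(
        response=response_name,
        coefficients=pd.Series(res.params[1:], index=Xf.columns),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_p=float(res.f_pvalue),
        residuals=pd.Series(res.resid, index=index),
        fitted=pd.Series(res.fittedvalues, index=index),
    )


# -------------------------------------------------------- permutation tests

def permutation_test_r2(
    y,
    X,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for the overall model R^2.

    The response rows are permuted ``n_perm`` times and the model R^2
    recomputed; p = (count(R^2_perm >= R^2_obs) + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(rng)
    Xf = _as_frame(X)
    yv = np.asarray(y, dtype=float)
    z = yv - yv.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("response has zero variance")
    q = _orthobasis(Xf.to_numpy(dtype=float) - Xf.to_numpy(dtype=float).mean(axis=0))
    r2_obs = float(z @ q @ q.T @ z) / ss
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)     # B x n
    proj = perms @ q                                          # B x r
    r2_perm = np.einsum("br,br->b", proj, proj) / ss
    return float((np.sum(r2_perm >= r2_obs - 1e-12) + 1) / (n_perm + 1))


# --------------------------------------------------------- forward selection

class ForwardSelector(BaseEstimator):
    """Forward selection of predictors with the double stopping rule.

    Candidates enter one at a time, each step adding the candidate with
    the largest R-squared gain (ties broken by lowest column index).  A
    candidate is accepted only if

    1. the permutation p-value of its marginal contribution (reduced-model
       residual permutation) is at or below ``alpha``, and
    2. the cumulative adjusted R-squared of the growing model does not
       exceed the adjusted R-squared of the global (all-candidate) model.

    Selection stops at the first violation, and nothing is selected unless
    the global model itself is significant at ``alpha``.

    Attributes
    ----------
    selected_ : list of column names in selection order.
    support_ : boolean mask over the input columns.
    records_ : DataFrame with one row per accepted step
        (variable, r2_cum, adj_r2_cum, p_enter).
    global_adj_r2_, global_p_ : the global-model statistics.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_perm: int = 999,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        rng = np.random.default_rng(self.random_state)
        Xf = _as_frame(X)
        names = list(Xf.columns)
        xmat = Xf.to_numpy(dtype=float)
        xmat = xmat - xmat.mean(axis=0)
        yv = np.asarray(y, dtype=float)
        z = yv - yv.mean()
        ss = float(z @ z)
        if ss == 0:
            raise ValueError("response has zero variance")
        n, m = xmat.shape

        self.n_features_in_ = m
        self.feature_names_in_ = np.asarray(names, dtype=object)
        r2_global = _r2(yv, xmat)
        p_global_cap = min(m, n - 2)
        self.global_adj_r2_ = adjusted_r2(r2_global, n, p_global_cap)
        self.global_p_ = permutation_test_r2(yv, xmat, self.n_perm, rng)

        selected: list[int] = []
        records = []
        if self.global_p_ <= self.alpha:
            r2_cum = 0.0
            q = np.zeros((n, 0))
            remaining = list(range(m))
            while remaining:
                z_res = z - q @ (q.T @ z)
                cand = xmat[:, remaining]
                cand_res = cand - q @ (q.T @ cand)
                norms = np.einsum("ij,ij->j", cand_res, cand_res)
                with np.errstate(invalid="ignore", divide="ignore"):
                    gains = (cand_res.T @ z_res) ** 2 / (norms * ss)
                gains = np.where(norms > 1e-12 * n, gains, -np.inf)
                best = int(np.argmax(gains))  # first max -> lowest index tie-break
                gain = float(gains[best])
                if not np.isfinite(gain) or gain <= 0:
                    break
                jcol = remaining[best]
                r2_new = r2_cum + gain
                adj_new = adjusted_r2(r2_new, n, len(selected) + 1)
                p_enter = self._marginal_p(
                    z, q, xmat[:, jcol], gain, rng
                )
                if p_enter > self.alpha or adj_new > self.global_adj_r2_ + 1e-10:
                    break
                selected.append(jcol)
                remaining.remove(jcol)
                records.append((names[jcol], r2_new, adj_new, p_enter))
                r2_cum = r2_new
                q = _orthobasis(xmat[:, selected])
                if len(selected) >= n - 2:
                    break

        self.selected_ = [names[j] for j in selected]
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[selected] = True
        self.records_ = pd.DataFrame(
            records, columns=["variable", "r2_cum", "adj_r2_cum", "p_enter"]
        )
        return self

    def _marginal_p(self, z, q, xj, gain_obs, rng) -> float:
        """Reduced-model residual permutation test of one candidate's gain."""
        n = len(z)
        fitted = q @ (q.T @ z)                       # current-model fit of z
        e = z - fitted
        xr = xj - q @ (q.T @ xj)
        xr_ss = float(xr @ xr)
        if xr_ss == 0:
            return 1.0
        perms = rng.permuted(np.tile(e, (self.n_perm, 1)), axis=1)
        zstar = fitted[None, :] + perms              # B x n, mean 0
        ss_star = np.einsum("bi,bi->b", zstar, zstar)
        num = (perms @ xr) ** 2                      # fitted _|_ xr
        gains = num / (xr_ss * ss_star)
        exceed = np.sum(gains >= gain_obs - 1e-12)
        return float((exceed + 1) / (self.n_perm + 1))

    def get_support(self):
        return self.support_

    def transform(self, X):
        return _as_frame(X).loc[:, self.selected_]


def forward_select(
    y,
    candidates,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> ForwardSelector:
    """Run :class:`ForwardSelector` and return the fitted selector."""
    return ForwardSelector(alpha=alpha, n_perm=n_perm, random_state=seed).fit(
        candidates, y
    )


# ----------------------------------------------------------------------- VIF

def variance_inflation(X) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j), regressing each column on the others.

    Perfectly collinear columns are reported as ``inf``.
    """
    Xf = _as_frame(X)
    if Xf.shape[1] < 2:
        raise ValueError("need at least 2 predictor columns")
    xmat = Xf.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(Xf.columns):
        others = np.delete(xmat, j, axis=1)
        r2_j = _r2(xmat[:, j], others)
        out[name] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return pd.Series(out, name="VIF")


# ------------------------------------------------------ variation partition

@dataclass
class VariationPartition:
    """Adjusted-R^2 fractions of one response: a = [E|S], b = [E n S],
    c = [S|E], d = residual.  ``b`` may be negative."""

    a: float
    b: float
    c: float
    d: float
    adj_env: float
    adj_spa: float
    adj_full: float
    p_env: float | None
    p_spa: float | None
    p_a: float | None
    p_c: float | None
    flags: list[str] = field(default_factory=list)


def _semipartial_p(
    yv: np.ndarray,
    x_cond: np.ndarray,
    x_add: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the R^2 gained by ``x_add`` over ``x_cond``,
    permuting residuals of the conditioning model."""
    z = yv - yv.mean()
    ss = float(z @ z)
    q_cond = _orthobasis(x_cond - x_cond.mean(axis=0))
    x_all = np.hstack([x_cond, x_add])
    gain_obs = _r2(yv, x_all) - _r2(yv, x_cond)
    fitted = q_cond @ (q_cond.T @ z)
    e = z - fitted
    q_all = _orthobasis(x_all - x_all.mean(axis=0))
    perms = rng.permuted(np.tile(e, (n_perm, 1)), axis=1)
    zstar = fitted[None, :] + perms
    ss_star = np.einsum("bi,bi->b", zstar, zstar)
    pc = zstar @ q_cond
    pa = zstar @ q_all
    gains = (
        np.einsum("br,br->b", pa, pa) - np.einsum("br,br->b", pc, pc)
    ) / ss_star
    return float((np.sum(gains >= gain_obs - 1e-12) + 1) / (n_perm + 1))


def variation_partition(
    y,
    env,
    spa,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> VariationPartition:
    """Partition a response's variation between two predictor sets.

    ``env`` and ``spa`` are DataFrames (possibly empty) of the selected
    environmental and spatial predictors.  Fractions are differences of
    Ezekiel-adjusted R^2 values:

        a = adjR2(E u S) - adjR2(S),  c = adjR2(E u S) - adjR2(E),
        b = adjR2(E) + adjR2(S) - adjR2(E u S),  d = 1 - adjR2(E u S).

    Testable fractions get permutation p-values: marginal models by
    permuting the response, semipartial fractions (a, c) by permuting the
    residuals of the conditioning model.
    """
    rng = np.random.default_rng(rng)
    env = _as_frame(env) if env is not None else pd.DataFrame(index=_as_frame(spa).index)
    spa = _as_frame(spa) if spa is not None else pd.DataFrame(index=env.index)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    flags = []
    pe = env.shape[1]
    ps = spa.shape[1]
    xe = env.to_numpy(dtype=float) if pe else np.zeros((n, 0))
    xs = spa.to_numpy(dtype=float) if ps else np.zeros((n, 0))
    x_all = np.hstack([xe, xs])
    if x_all.shape[1] == 0:
        raise ValueError("both predictor sets empty")
    q_all = _orthobasis(x_all - x_all.mean(axis=0))
    rank_all = q_all.shape[1]
    if n <= rank_all + 1:
        raise ValueError("combined model has too few residual degrees of freedom")

    def _adj(xmat, p_cols):
        if p_cols == 0:
            return 0.0
        return adjusted_r2(_r2(yv, xmat), n, p_cols)

    adj_e = _adj(xe, pe)
    adj_s = _adj(xs, ps)
    # the union model's df uses the rank of the combined matrix so that
    # duplicated predictors across sets do not inflate p
    adj_es = adjusted_r2(_r2(yv, x_all), n, rank_all)
    if pe == 0:
        flags.append("environment set empty: adjR2(E) = 0")
    if ps == 0:
        flags.append("spatial set empty: adjR2(S) = 0")

    a = adj_es - adj_s
    c = adj_es - adj_e
    b = adj_e + adj_s - adj_es
    d = 1.0 - adj_es

    p_env = permutation_test_r2(yv, xe, n_perm, rng) if pe else None
    p_spa = permutation_test_r2(yv, xs, n_perm, rng) if ps else None
    p_a = _semipartial_p(yv, xs, xe, n_perm, rng) if pe and ps else None
    p_c = _semipartial_p(yv, xe, xs, n_perm, rng) if pe and ps else None
    return VariationPartition(
        a=a, b=b, c=c, d=d,
        adj_env=adj_e, adj_spa=adj_s, adj_full=adj_es,
        p_env=p_env, p_spa=p_spa, p_a=p_a, p_c=p_c,
        flags=flags,
    )


# ---------------------------------------------------------------- reporting

def signed_variable_string(selected: list[str], coefficients: pd.Series) -> str:
    """Render selected variables with the signs of their final coefficients,
    e.g. ``"MAP + MAPVAR - ALTVAR"``."""
    parts = []
    for i, name in enumerate(selected):
        neg = coefficients[name] < 0
        if i == 0:
            parts.append(("-" if neg else "") + name)
        else:
            parts.append(("- " if neg else "+ ") + name)
    return " ".join(parts)


def table1_report(results: dict[str, dict[str, tuple]]) -> pd.DataFrame:
    """Selection summary table: one row per index x factor set.

    ``results[index][factor]`` is a ``(selector, fit_or_None)`` pair from
    forward selection and the OLS fit on the selected variables.  Columns:
    selected variables in selection order with coefficient signs, adjusted
    R^2, the global-model F statistic of the selected model, and the
    selected model's permutation p.
    """
    rows = []
    for index_name, factors in results.items():
        for factor, (selector, fit) in factors.items():
            if fit is None or not selector.selected_:
                rows.append((index_name, factor, "(none)", 0.0, np.nan, np.nan))
                continue
            rows.append(
                (
                    index_name,
                    factor,
                    signed_variable_string(selector.selected_, fit.coefficients),
                    fit.adj_r2,
                    fit.f_stat,
                    fit.f_p,
                )
            )
    return pd.DataFrame(
        rows, columns=["index", "factor", "selected", "adj_r2", "F", "p"]
    )
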
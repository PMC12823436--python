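"""Cross-cutting association statistics.

Partial Spearman correlation with covariate adjustment (rank first, then
residualize both ranked variables on the covariate design, then Pearson on
the residuals — the convention of the ppcor-style tools), Benjamini-Hochberg
adjustment, plain Spearman and nonparametric group-difference tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_1d_float


@dataclass
class PartialCorrelationResult:
    x_id: str
    y_id: str
    covariate_ids: tuple
    rho: float
    p: float
    n_used: int
    q: float | None = None


def spearman(x, y):
    """Average-rank Spearman correlation with t-approximation p-value.

    Pairs with a missing value in either vector are dropped (pairwise
    complete).  Requires >= 4 complete pairs and non-constant inputs.
    """
    x = as_1d_float(x, "x")
    y = as_1d_float(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("spearman needs >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman: constant input vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_approx_p(rho, df=x.size - 2)


def _t_approx_p(r: float, df: int) -> float:
    r = min(max(r, -1.0), 1.0)
    if df <= 0:
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df))


def partial_spearman(x, y, covariates=None, x_id="x", y_id="y") -> PartialCorrelationResult:
    """Partial Spearman correlation of x and y given covariates.

    x and y are rank-transformed (average ranks), each is residualized on the
    covariate design (with intercept) by OLS, and the Pearson correlation of
    the two residual vectors is returned with a t-approximation p-value at
    df = n - n_covariates - 2.  With no covariates this equals plain Spearman.
    """
    x = as_1d_float(x, "x")
    y = as_1d_float(y, "y")
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.empty((x.size, 0))
        cov_ids = ()
    else:
        Z = np.column_stack([as_1d_float(c, "covariate") for c in np.atleast_2d(np.asarray(covariates, float).T).T]) \
            if np.asarray(covariates).ndim == 1 else np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        cov_ids = tuple(f"z{i}" for i in range(Z.shape[1]))
    if isinstance(covariates, pd.DataFrame):
        cov_ids = tuple(covariates.columns)
        Z = covariates.to_numpy(float)
    k = Z.shape[1]
    ok = ~(np.isnan(x) | np.isnan(y))
    if k:
        ok &= ~np.isnan(Z).any(axis=1)
    x, y = x[ok], y[ok]
    Z = Z[ok]
    n = x.size
    if n < k + 3:
        raise ValueError(f"partial_spearman needs >= {k + 3} complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("partial_spearman: constant input after filtering")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    design = np.column_stack([np.ones(n), Z])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex, ey = rx - design @ beta_x, ry - design @ beta_y
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValueError("partial_spearman: residuals constant (rank-deficient design?)")
    rho = float((ex @ ey) / denom)
    p = _t_approx_p(rho, df=n - k - 2)
    return PartialCorrelationResult(x_id, y_id, cov_ids, rho, p, n)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone non-decreasing in sorted order, capped at 1, input order
    restored.  NaN entries propagate as NaN with a warning and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    shape = p.shape
    p = p.ravel()
    nan_mask = np.isnan(p)
    if nan_mask.any():
        warnings.warn("bh_adjust: NaN p-values propagated as NaN")
    valid = p[~nan_mask]
    if np.any((valid < 0) | (valid > 1)):
        raise ValueError("p-values must be in [0, 1]")
    q = np.full_like(p, np.nan)
    m = valid.size
    if m:
        order = np.argsort(valid, kind="mergesort")
        ranked = valid[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[~nan_mask] = qv
    return q.reshape(shape)


def _ranksum_method(a, b) -> str:
    """Exact rank-sum enumeration for small tie-free samples, else normal
    approximation (exact is intractable and unnecessary at larger n)."""
    pooled = np.concatenate([a, b])
    small = len(a) <= 25 and len(b) <= 25
    no_ties = np.unique(pooled).size == pooled.size
    return "exact" if small and no_ties else "asymptotic"


@dataclass
class GroupDifferenceResult:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame
    dropped_groups: list = field(default_factory=list)


def group_difference_tests(values, groups, min_group_size: int = 2) -> GroupDifferenceResult:
    """Kruskal-Wallis omnibus (tie-corrected) plus pairwise two-sided
    rank-sum tests with BH adjustment across pairs.

    Groups smaller than ``min_group_size`` are dropped with a warning.
    Effect direction is reported as the difference of group medians.
    """
    values = as_1d_float(values, "values")
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    by_group = {}
    dropped = []
    for g in pd.unique(groups):
        vals = values[groups == g]
        if vals.size < min_group_size:
            dropped.append(g)
            warnings.warn(f"group_difference_tests: group {g!r} has < {min_group_size} members; dropped")
        else:
            by_group[g] = vals
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups with enough members")
    names = list(by_group)
    if all(np.array_equal(np.sort(by_group[g]), np.sort(by_group[names[0]])) for g in names):
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        omnibus_stat, omnibus_p = stats.kruskal(*by_group.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = by_group[names[i]], by_group[names[j]]
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method=_ranksum_method(a, b))
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": float(res.statistic), "p": float(res.pvalue),
                "median_difference": float(np.median(a) - np.median(b)),
            })
    pw = pd.DataFrame(rows)
    pw["q"] = bh_adjust(pw["p"].to_numpy())
    return GroupDifferenceResult(float(omnibus_stat), float(omnibus_p), pw, dropped)


def pairwise_spearman_matrix(A: pd.DataFrame, B: pd.DataFrame):
    """All-pairs Spearman correlations between columns of A and columns of B
    (shared rows), vectorized via ranked matrices.

    Returns (rho, p) DataFrames of shape (A columns x B columns).
    """
    if not A.index.equals(B.index):
        B = B.loc[A.index]
    n = len(A)
    ra = np.apply_along_axis(stats.rankdata, 0, A.to_numpy(float))
    rb = np.apply_along_axis(stats.rankdata, 0, B.to_numpy(float))
    ra = (ra - ra.mean(axis=0)) / ra.std(axis=0, ddof=0)
    rb = (rb - rb.mean(axis=0)) / rb.std(axis=0, ddof=0)
    rho = (ra.T @ rb) / n
    rho = np.clip(rho, -1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return (pd.DataFrame(rho, index=A.columns, columns=B.columns),
            pd.DataFrame(p, index=A.columns, columns=B.columns))
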
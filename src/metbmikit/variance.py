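"""Per-layer variance explained via nested cross-validated penalized regression.

For a numeric target and one omics layer, an outer k-fold loop holds out one
fold at a time while an inner k-fold grid search over the penalty path picks
the penalty minimizing inner-CV mean squared error; hold-out R^2 is then
computed on the untouched outer fold.  The median over outer folds is the
layer's variance explained.  Layers are compared by two-sided rank-sum tests
on the per-fold R^2 vectors with Benjamini-Hochberg correction and a compact
letter display.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed, logger
from .io import OmicsLayer
from .penalized import (Standardizer, cv_choose_penalty, fit_penalized,
                        holdout_r2, make_lambda_grid)
from .stats import _ranksum_method, bh_adjust


@dataclass
class NestedCVResult:
    target_name: str
    layer_name: str
    penalty_kind: str
    per_fold_r2: np.ndarray
    median_r2: float
    chosen_penalty_per_fold: np.ndarray
    fold_assignment: np.ndarray
    seed: int
    fold_coef_hashes: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.per_fold_r2) != len(self.chosen_penalty_per_fold):
            raise ValueError("per-fold vectors must have equal length")


def _decile_strata(y: np.ndarray, k: int) -> np.ndarray:
    """Target-decile labels used to stratify outer folds (seeded, stable)."""
    n_bins = min(10, max(2, len(y) // (2 * k)))
    try:
        return pd.qcut(y, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        return np.zeros(len(y), dtype=int)


def nested_cv_r2(target, layer, penalty_kind: str = "ridge",
                 k_outer: int = 10, k_inner: int = 10,
                 grid_length: int = 100, eps: float = 1e-5,
                 lambda_range=None, seed: int = 0,
                 target_name: str = "target",
                 fold_assignment=None) -> NestedCVResult:
    """Nested cross-validated hold-out R^2 of ``target`` from one layer.

    Features are standardized on training folds only; constant features are
    dropped with a log entry.  Negative hold-out R^2 is reported as-is.
    Outer folds are seeded and stratified on target deciles; a precomputed
    ``fold_assignment`` (per-sample outer-fold index) can be supplied to
    reuse a fixed partition.
    """
    if isinstance(layer, OmicsLayer):
        X = layer.values
        layer_name = layer.layer_name
    else:
        X = np.asarray(layer, dtype=float)
        layer_name = "layer"
    y = np.asarray(target, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("target length must match layer rows")
    if np.ptp(y) == 0:
        raise ValueError("constant target: variance explained undefined")
    if len(y) < 2 * k_outer:
        raise ValueError(f"need n >= {2 * k_outer} for {k_outer} outer folds")

    const = np.ptp(X, axis=0) == 0
    if const.any():
        logger.info("nested_cv_r2: dropping %d constant feature(s)", int(const.sum()))
        X = X[:, ~const]

    if fold_assignment is None:
        strata = _decile_strata(y, k_outer)
        skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed % 2**31)
        fold_assignment = np.empty(len(y), dtype=int)
        splits = []
        for fold_idx, (tr, ho) in enumerate(skf.split(X, strata)):
            fold_assignment[ho] = fold_idx
            splits.append((tr, ho))
    else:
        fold_assignment = np.asarray(fold_assignment, dtype=int)
        if len(fold_assignment) != len(y):
            raise ValueError("fold_assignment length must match target length")
        k_outer = int(fold_assignment.max()) + 1
        splits = [(np.flatnonzero(fold_assignment != k), np.flatnonzero(fold_assignment == k))
                  for k in range(k_outer)]
    r2s, lams, hashes = [], [], []
    for fold_idx, (tr, ho) in enumerate(splits):
        Xtr, ytr = X[tr], y[tr]
        std = Standardizer.fit(Xtr)
        grid = make_lambda_grid(std.transform(Xtr), ytr - ytr.mean(),
                                penalty_kind, grid_length, eps, lambda_range)
        lam, _ = cv_choose_penalty(Xtr, ytr, penalty_kind, grid, k=k_inner,
                                   seed=derive_seed(seed, "inner", fold_idx))
        fit = fit_penalized(Xtr, ytr, penalty_kind, lam)
        r2s.append(holdout_r2(y[ho], fit.predict(X[ho])))
        lams.append(lam)
        hashes.append(hashlib.sha256(np.ascontiguousarray(fit.coef_std).tobytes()).hexdigest())
    r2s = np.array(r2s)
    return NestedCVResult(target_name, layer_name, penalty_kind, r2s,
                          float(np.median(r2s)), np.array(lams),
                          fold_assignment, seed, hashes)


def exclude_self_layer(target_feature_id: str, layers: dict) -> dict:
    """Drop the layer containing the target feature from a layer mapping.

    Raises if the id resolves to multiple layers; a target absent from every
    layer (e.g. gene richness) leaves the mapping unchanged.
    """
    holders = [name for name, layer in layers.items()
               if target_feature_id in layer.feature_ids]
    if len(holders) > 1:
        raise ValueError(
            f"feature {target_feature_id!r} appears in multiple layers: {holders}")
    return {name: layer for name, layer in layers.items() if name not in holders}


def _maximal_cliques(adj: np.ndarray):
    """Bron-Kerbosch maximal cliques of a small undirected graph."""
    n = adj.shape[0]
    cliques = []

    def bk(r, p, x):
        if not p and not x:
            cliques.append(sorted(r))
            return
        for v in list(p):
            nb = {u for u in range(n) if adj[v, u] and u != v}
            bk(r | {v}, p & nb, x & nb)
            p = p - {v}
            x = x | {v}

    bk(set(), set(range(n)), set())
    return cliques


def compare_layer_performance(results, alpha: float = 0.05):
    """Pairwise two-sided rank-sum tests on per-fold R^2, BH-corrected,
    with a compact letter display (layers sharing a letter do not differ
    significantly at the adjusted ``alpha``).
    """
    if len(results) < 2:
        raise ValueError("need >= 2 layers to compare")
    n_folds = {len(r.per_fold_r2) for r in results}
    if len(n_folds) != 1:
        raise ValueError("layers must have equal fold counts")
    if n_folds.pop() < 3:
        raise ValueError("need >= 3 folds per layer")
    names = [r.layer_name for r in results]
    rows = []
    for i, j in itertools.combinations(range(len(results)), 2):
        a, b = results[i].per_fold_r2, results[j].per_fold_r2
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0
            stat = float(len(a) * len(b) / 2)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method=_ranksum_method(a, b))
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"layer_a": names[i], "layer_b": names[j], "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())

    # not-significantly-different graph -> letters from maximal cliques
    k = len(results)
    adj = np.eye(k, dtype=bool)
    for row in table.itertuples():
        i, j = names.index(row.layer_a), names.index(row.layer_b)
        if row.q >= alpha:
            adj[i, j] = adj[j, i] = True
    cliques = sorted(_maximal_cliques(adj))
    letters = {name: "" for name in names}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for member in clique:
            letters[names[member]] += letter
    return table, letters
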
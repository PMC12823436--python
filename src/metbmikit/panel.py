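"""Metabolite panel reduction.

Two complementary stages narrow the metabolite space to a compact panel:

1. an all-relevant shadow-feature stage (Boruta-style): each run appends a
   permuted shadow copy of every still-active feature, computes permutation
   importances from a tree-ensemble regressor and records a hit when a real
   feature beats the best shadow; features are confirmed/rejected by
   Bonferroni-corrected two-sided binomial tests on hit counts, iterating
   until resolved or the run budget is exhausted;
2. a stability stage: an L1-penalized model with CV-chosen penalty fitted on
   seeded 80% resamples, recording each feature's selection frequency.

``assemble_panel`` turns the two stages into a final panel and refits the
metBMI ridge pipeline on the original split to compare the panel's hold-out
R^2 against the full model's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LassoCV, Ridge
from sklearn.utils.validation import check_is_fitted

from ._utils import derive_seed, logger
from .metbmi import MetBMIRegressor
from .penalized import holdout_r2


def _permutation_importance(model, X, y, rng, chunk: int = 60):
    """MSE increase when each column is permuted (one shared permutation).

    Permuted variants are scored in stacked batches so tree-ensemble
    predict overhead is paid once per chunk, not once per feature.
    """
    base = np.mean((model.predict(X) - y) ** 2)
    perm = rng.permutation(X.shape[0])
    p = X.shape[1]
    imp = np.empty(p)
    for start in range(0, p, chunk):
        cols = range(start, min(start + chunk, p))
        stack = []
        for j in cols:
            Xp = X.copy()
            Xp[:, j] = Xp[perm, j]
            stack.append(Xp)
        preds = model.predict(np.vstack(stack)).reshape(len(stack), -1)
        imp[start:start + len(stack)] = np.mean((preds - y) ** 2, axis=1) - base
    return imp


def _trees_permutation_importance(X, y, n_estimators, seed, rng):
    """Permutation importance of an extremely-randomized-trees regressor,
    scored on a held-out 30% of rows (training-set importance rewards
    memorization and blunts the real-vs-shadow contrast)."""
    n = X.shape[0]
    order = rng.permutation(n)
    cut = max(int(0.7 * n), n - 400)
    tr, va = order[:cut], order[cut:]
    model = ExtraTreesRegressor(n_estimators=n_estimators, max_features="sqrt",
                                min_samples_leaf=5, n_jobs=1,
                                random_state=seed).fit(X[tr], y[tr])
    return _permutation_importance(model, X[va], y[va], rng)


class ShadowFeatureSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature selection against permuted shadow features.

    Parameters
    ----------
    n_runs : maximum number of importance-source runs (budget; iteration
        stops early once every feature is resolved).
    alpha : per-iteration significance level for the binomial hit tests,
        Bonferroni-corrected across candidate features.
    importance : 'permutation_trees' (permutation importance of an
        extremely-randomized-trees regressor, default) or 'ridge' (absolute
        standardized ridge coefficients) — the importance source is
        pluggable.
    n_estimators : ensemble size for the default importance source.
    seed : master seed; per-run streams are derived from it.

    Fitted attributes: ``confirmed_ids_``, ``tentative_ids_``,
    ``rejected_ids_`` (a partition of the candidate features), ``hits_``,
    ``n_iterations_`` and ``support_``.
    """

    def __init__(self, n_runs: int = 999, alpha: float = 0.05,
                 importance: str = "permutation_trees", n_estimators: int = 256,
                 burn_in: int = 12, seed: int = 0):
        self.n_runs = n_runs
        self.alpha = alpha
        self.importance = importance
        self.n_estimators = n_estimators
        self.burn_in = burn_in
        self.seed = seed

    def _importances(self, X, y, rng, run_idx):
        if self.importance == "permutation_trees":
            return _trees_permutation_importance(
                X, y, self.n_estimators, derive_seed(self.seed, "trees", run_idx), rng)
        if self.importance == "ridge":
            # refit on a per-run row subsample so importances vary across
            # runs and the binomial hit model stays valid
            idx = rng.choice(X.shape[0], size=int(0.7 * X.shape[0]), replace=False)
            Xs, ys = X[idx], y[idx]
            sd = Xs.std(axis=0)
            Xs = (Xs - Xs.mean(axis=0)) / np.where(sd == 0, 1, sd)
            coef = Ridge(alpha=1.0).fit(Xs, ys - ys.mean()).coef_
            return np.abs(coef)
        raise ValueError(f"unknown importance source {self.importance!r}")

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 50:
            raise ValueError("shadow_feature_selection needs n >= 50")
        if names is None:
            names = [f"f{j}" for j in range(p)]
        self.feature_names_in_ = np.array(names)
        self.n_features_in_ = p

        # smallest run count at which a decision is possible at all
        min_runs = int(np.ceil(np.log(self.alpha / p) / np.log(0.5)))
        if self.n_runs < min_runs:
            raise ValueError(
                f"n_runs={self.n_runs} cannot reach a decision at alpha={self.alpha} "
                f"with {p} features (needs >= {min_runs})")

        status = np.zeros(p, dtype=int)     # 0 tentative, 1 confirmed, -1 rejected
        hits = np.zeros(p, dtype=int)
        rng = np.random.default_rng(derive_seed(self.seed, "shadow"))
        t = 0
        while t < self.n_runs and (status == 0).any():
            t += 1
            active = status == 0
            Xa = X[:, active]
            # shadow copy of every feature (not just active ones), so the
            # shadow-max null threshold keeps its severity as features resolve
            shadow = X.copy()
            for j in range(shadow.shape[1]):
                rng.shuffle(shadow[:, j])
            imp = self._importances(np.hstack([Xa, shadow]), y, rng, t)
            real_imp, shadow_imp = imp[: Xa.shape[1]], imp[Xa.shape[1]:]
            hits[active] += real_imp > shadow_imp.max()
            if t < self.burn_in:
                # no decisions before the burn-in: testing at every run from
                # the start spends the sequential alpha on lucky streaks
                continue
            # Bonferroni-corrected binomial decisions on hit counts
            thr = self.alpha / p
            k = hits[active]
            confirm = sps.binom.sf(k - 1, t, 0.5) < thr      # P(X >= k)
            reject = sps.binom.cdf(k, t, 0.5) < thr          # P(X <= k)
            idx = np.flatnonzero(active)
            status[idx[confirm]] = 1
            status[idx[reject]] = -1
        self.n_iterations_ = t
        self.hits_ = hits
        self.confirmed_ids_ = [names[j] for j in np.flatnonzero(status == 1)]
        self.tentative_ids_ = [names[j] for j in np.flatnonzero(status == 0)]
        self.rejected_ids_ = [names[j] for j in np.flatnonzero(status == -1)]
        self.support_ = status == 1
        logger.info("shadow selection: %d confirmed, %d tentative, %d rejected in %d runs",
                    len(self.confirmed_ids_), len(self.tentative_ids_),
                    len(self.rejected_ids_), t)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def shadow_feature_selection(features: pd.DataFrame, target, n_runs: int = 999,
                             alpha: float = 0.05, seed: int = 0,
                             **kwargs) -> ShadowFeatureSelector:
    return ShadowFeatureSelector(n_runs=n_runs, alpha=alpha, seed=seed,
                                 **kwargs).fit(features, target)


def iterative_sparse_stability(features: pd.DataFrame, target,
                               n_resamples: int = 10, subsample: float = 0.8,
                               cv: int = 5, seed: int = 0) -> pd.Series:
    """Selection frequency of each feature over L1 fits on seeded resamples.

    Each of ``n_resamples`` draws an 80% subsample without replacement and
    fits a lasso with CV-chosen penalty on standardized features; frequency
    is the fraction of resamples with a nonzero coefficient.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    n = len(y)
    if n < 50:
        raise ValueError("iterative_sparse_stability needs n >= 50")
    counts = np.zeros(X.shape[1])
    for r in range(n_resamples):
        rng = np.random.default_rng(derive_seed(seed, "stability", r))
        idx = rng.choice(n, size=int(round(subsample * n)), replace=False)
        ys = y[idx]
        if np.ptp(ys) == 0:
            raise ValueError(f"degenerate resample {r}: constant target")
        Xs = X[idx]
        sd = Xs.std(axis=0)
        Xs = (Xs - Xs.mean(axis=0)) / np.where(sd == 0, 1, sd)
        model = LassoCV(cv=cv, alphas=50, random_state=derive_seed(seed, "lassocv", r),
                        max_iter=5000).fit(Xs, ys)
        counts += model.coef_ != 0
    names = (features.columns if isinstance(features, pd.DataFrame)
             else [f"f{j}" for j in range(X.shape[1])])
    return pd.Series(counts / n_resamples, index=names, name="selection_frequency")


@dataclass
class PanelSelectionResult:
    confirmed_ids: list
    tentative_ids: list
    rejected_ids: list
    selection_frequency: pd.Series
    final_panel: list
    panel_r2: float
    full_model_r2: float
    rule: str


def assemble_panel(selector: ShadowFeatureSelector, frequencies: pd.Series,
                   metabolome: pd.DataFrame, cohort: pd.DataFrame,
                   train_ids, test_ids, rule: str = "confirmed",
                   frequency_threshold: float = 1.0,
                   penalty: str = "ridge", seed: int = 0) -> PanelSelectionResult:
    """Assemble the final panel and verify retained explanatory power.

    ``rule='confirmed'`` (default): the shadow-stage confirmed set, ranked
    by selection frequency then |Spearman rho| with BMI.  ``rule='union'``:
    confirmed set plus features consistently selected across all stability
    resamples (a three-source union with the ridge model that refits below).
    Both the panel and the full candidate set are refitted with the metBMI
    ridge pipeline on the original train/test split and their hold-out R^2
    reported side by side.
    """
    candidates = list(selector.feature_names_in_)
    confirmed = list(selector.confirmed_ids_)
    if rule == "confirmed":
        panel = confirmed
    elif rule == "union":
        consistent = frequencies[frequencies >= frequency_threshold].index.tolist()
        panel = sorted(set(confirmed) | set(consistent), key=candidates.index)
    else:
        raise ValueError(f"unknown panel rule {rule!r}")
    if not panel:
        raise ValueError("empty panel; no feature was confirmed")

    bmi = cohort["BMI"]
    rho = {f: abs(sps.spearmanr(metabolome[f], bmi).statistic) for f in panel}
    panel = sorted(panel, key=lambda f: (-frequencies.get(f, 0.0), -rho[f]))

    ytr = cohort.loc[train_ids, "BMI"].to_numpy(float)
    yte = cohort.loc[test_ids, "BMI"].to_numpy(float)

    def refit_r2(feature_ids):
        est = MetBMIRegressor(penalty=penalty, seed=seed).fit(
            metabolome.loc[train_ids, feature_ids], ytr)
        return holdout_r2(yte, est.predict(metabolome.loc[test_ids, feature_ids]))

    panel_r2 = refit_r2(panel)
    full_r2 = refit_r2(candidates)
    logger.info("panel of %d features: R^2 %.3f vs full-model %.3f",
                len(panel), panel_r2, full_r2)
    return PanelSelectionResult(
        confirmed_ids=confirmed, tentative_ids=list(selector.tentative_ids_),
        rejected_ids=list(selector.rejected_ids_),
        selection_frequency=frequencies, final_panel=panel,
        panel_r2=float(panel_r2), full_model_r2=float(full_r2), rule=rule,
    )
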
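"""The metabolome-informed BMI (metBMI) model.

Pipeline: (1) pre-filter metabolites by Spearman association with measured
BMI; (2) draw a sex x WHO-BMI-class balanced training pool limited by the
smallest stratum; (3) split it 75/25 into training and test sets, routing
everyone else to the non-test set (test + non-test = extended test set);
(4) fit a cross-validated penalized regression of BMI on the pre-filtered
metabolites; (5) predict metBMI cohort-wide; (6) residualize metBMI on age,
sex and measured BMI and classify the residual tails (HmetBMI / LmetBMI,
others keeping their WHO BMI class).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from ._utils import logger
from .penalized import (Standardizer, cv_choose_penalty, fit_penalized,
                        holdout_r2, make_lambda_grid)
from .stats import bh_adjust

WHO_EDGES = (18.5, 25.0, 30.0)
WHO_LABELS = ("normal weight", "overweight", "obesity")


def who_bmi_class(bmi) -> np.ndarray:
    """WHO BMI class labels; BMI below 18.5 is folded into normal weight
    (the cohort design admits essentially no underweight participants)."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.where(bmi >= 30.0, "obesity", np.where(bmi >= 25.0, "overweight", "normal weight"))
    return out.astype(object)


# ---------------------------------------------------------------------------
# pre-filter
# ---------------------------------------------------------------------------

def select_bmi_metabolites(metabolome: pd.DataFrame, bmi,
                           rho_threshold: float = 0.1,
                           q_threshold: float = 0.05,
                           use_q_gate: bool = True,
                           min_pairs: int = 30) -> pd.DataFrame:
    """Metabolites associated with BMI: |Spearman rho| > threshold and
    (optionally) BH-adjusted p < q_threshold.

    Returns a DataFrame (metabolite, rho, p, q, n) sorted by |rho|
    descending.  An empty result raises with advice to relax thresholds.
    """
    bmi = np.asarray(bmi, dtype=float).ravel()
    rows = []
    for col in metabolome.columns:
        x = metabolome[col].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(bmi))
        if ok.sum() < min_pairs:
            raise ValueError(f"metabolite {col!r}: only {int(ok.sum())} paired values (< {min_pairs})")
        rho, p = sps.spearmanr(x[ok], bmi[ok])
        rows.append({"metabolite": col, "rho": float(rho), "p": float(p), "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    keep = table["rho"].abs() > rho_threshold
    if use_q_gate:
        keep &= table["q"] < q_threshold
    selected = table[keep].sort_values("rho", key=np.abs, ascending=False).reset_index(drop=True)
    if selected.empty:
        raise ValueError(
            f"no metabolite passes |rho| > {rho_threshold} and q < {q_threshold}; "
            "consider relaxing the thresholds")
    logger.info("select_bmi_metabolites: %d / %d retained", len(selected), len(table))
    return selected


# ---------------------------------------------------------------------------
# balanced sampling and splitting
# ---------------------------------------------------------------------------

def _stratum_labels(cohort: pd.DataFrame) -> pd.Series:
    """Six strata = {female, male} x WHO class; BMI < 18.5 -> NaN (no stratum)."""
    bmi = cohort["BMI"].to_numpy(float)
    sex = cohort["sex"].to_numpy()
    labels = pd.Series(index=cohort.index, dtype=object)
    cls = np.where(bmi >= 30.0, "obesity",
                   np.where(bmi >= 25.0, "overweight",
                            np.where(bmi >= 18.5, "normal weight", None)))
    for i, (s, c) in enumerate(zip(sex, cls)):
        labels.iloc[i] = None if c is None else f"{'male' if s == 1 else 'female'}/{c}"
    return labels


@dataclass
class BalancedPool:
    pool_ids: list
    strata_counts: dict        # available samples per stratum (6 entries)
    sampled_per_stratum: int   # = size of the smallest stratum
    outside_strata_ids: list   # BMI below the lowest stratum edge
    stratum_of: pd.Series


def balanced_strata_sample(cohort: pd.DataFrame, seed: int = 0) -> BalancedPool:
    """Sample equal numbers from the six sex x WHO-BMI strata, limited by the
    smallest stratum, without replacement.  Samples outside all strata
    (BMI < 18.5) are routed to the non-test set."""
    labels = _stratum_labels(cohort)
    expected = [f"{s}/{c}" for s in ("female", "male") for c in WHO_LABELS]
    counts = {name: int((labels == name).sum()) for name in expected}
    empty = [name for name, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty stratum(s): {empty}")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    pool = []
    for name in expected:
        members = labels.index[labels == name].to_numpy()
        pool.extend(rng.choice(members, size=m, replace=False).tolist())
    outside = labels.index[labels.isna()].tolist()
    logger.info("balanced_strata_sample: smallest stratum %d -> pool %d; %d outside strata",
                m, len(pool), len(outside))
    return BalancedPool(pool, counts, m, outside, labels)


def split_train_test(pool: BalancedPool, cohort: pd.DataFrame,
                     train_fraction: float = 0.75, seed: int = 0):
    """Stratified 75/25 split of the balanced pool; extended test set =
    test set plus every cohort sample outside the pool."""
    if len(pool.pool_ids) < 8:
        raise ValueError("pool too small to split")
    strata = pool.stratum_of.loc[pool.pool_ids]
    train_ids, test_ids = train_test_split(
        list(pool.pool_ids), train_size=train_fraction,
        stratify=strata.to_numpy(), random_state=seed % 2**31)
    non_pool = [s for s in cohort.index if s not in set(pool.pool_ids)]
    extended_test = list(test_ids) + non_pool
    return list(train_ids), list(test_ids), extended_test


# ---------------------------------------------------------------------------
# penalized BMI regression
# ---------------------------------------------------------------------------

class MetBMIRegressor(RegressorMixin, BaseEstimator):
    """Cross-validated penalized regression of BMI on metabolite intensities.

    Follows the sklearn estimator contract: ``fit(X, y)`` standardizes
    features internally, picks the penalty on a log-spaced grid by k-fold CV
    minimizing mean squared error (ties toward the larger penalty) and
    refits on the full training data; ``predict`` applies the stored
    standardization constants, so predictions are deterministic.

    Parameters
    ----------
    penalty : 'ridge' (default) or 'lasso'.
    grid_length, eps : grid of ``grid_length`` penalties from the
        data-derived lambda_max down to lambda_max * eps.
    lambda_range : optional absolute (lo, hi) penalty range overriding the
        min-ratio grid.
    k_cv : CV folds used for penalty choice.
    seed : fold-assignment seed.
    """

    def __init__(self, penalty: str = "ridge", grid_length: int = 100,
                 eps: float = 1e-5, lambda_range=None, k_cv: int = 10, seed: int = 0):
        self.penalty = penalty
        self.grid_length = grid_length
        self.eps = eps
        self.lambda_range = lambda_range
        self.k_cv = k_cv
        self.seed = seed

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per target value")
        bad = ~np.isfinite(X)
        if bad.any():
            j = int(np.argwhere(bad.any(axis=0)).ravel()[0])
            name = names[j] if names else f"column {j}"
            raise ValueError(f"non-finite values in feature {name}")
        if not np.isfinite(y).all():
            raise ValueError("non-finite values in target")
        self.feature_names_in_ = np.array(names) if names else None
        self.n_features_in_ = X.shape[1]
        std = Standardizer.fit(X)
        grid = make_lambda_grid(std.transform(X), y - y.mean(), self.penalty,
                                self.grid_length, self.eps, self.lambda_range)
        self.alpha_, self.cv_mse_path_ = cv_choose_penalty(
            X, y, self.penalty, grid, k=self.k_cv, seed=self.seed)
        self.lambda_grid_ = grid
        self._fit = fit_penalized(X, y, self.penalty, self.alpha_)
        # expose raw-scale coefficients so the linear score is transparent
        self.coef_ = self._fit.coef_std / self._fit.standardizer.sd_
        self.intercept_ = float(self._fit.intercept_centered
                                - (self._fit.standardizer.mean_ * self.coef_).sum())
        self.feature_means_ = self._fit.standardizer.mean_
        self.feature_sds_ = self._fit.standardizer.sd_
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame) and self.feature_names_in_ is not None:
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing required metabolite(s): {missing}")
            X = X[list(self.feature_names_in_)]
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


@dataclass
class MetBMIModel:
    """Fitted metBMI model with full split and penalty provenance."""

    prefilter_ids: list
    strata_counts: dict
    train_ids: list
    test_ids: list
    non_test_ids: list
    penalty_kind: str
    chosen_penalty: float
    coefficients: dict          # feature -> raw-scale coefficient, plus "(intercept)"
    test_r2: float
    seed: int
    estimator: MetBMIRegressor | None = None

    def to_json(self, path) -> None:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "estimator"}
        if self.estimator is not None:
            payload["standardization"] = {
                "means": self.estimator.feature_means_.tolist(),
                "sds": self.estimator.feature_sds_.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def fit_metbmi(metabolome: pd.DataFrame, cohort: pd.DataFrame,
               prefilter_ids, train_ids, test_ids, non_test_ids=None,
               penalty: str = "ridge", grid_length: int = 100,
               k_cv: int = 10, seed: int = 0) -> MetBMIModel:
    """Fit the metBMI model on the training split and record hold-out R^2
    on the untouched test set."""
    prefilter_ids = list(prefilter_ids)
    if not prefilter_ids:
        raise ValueError("empty metabolite pre-filter")
    Xtr = metabolome.loc[train_ids, prefilter_ids]
    ytr = cohort.loc[train_ids, "BMI"].to_numpy(float)
    est = MetBMIRegressor(penalty=penalty, grid_length=grid_length,
                          k_cv=k_cv, seed=seed).fit(Xtr, ytr)
    yte = cohort.loc[test_ids, "BMI"].to_numpy(float)
    test_r2 = holdout_r2(yte, est.predict(metabolome.loc[test_ids, prefilter_ids]))
    coeffs = {"(intercept)": est.intercept_}
    coeffs.update({f: float(c) for f, c in zip(prefilter_ids, est.coef_)})
    return MetBMIModel(
        prefilter_ids=prefilter_ids,
        strata_counts={},
        train_ids=list(train_ids), test_ids=list(test_ids),
        non_test_ids=list(non_test_ids or []),
        penalty_kind=penalty, chosen_penalty=est.alpha_,
        coefficients=coeffs, test_r2=float(test_r2), seed=seed,
        estimator=est,
    )


def predict_metbmi(model: MetBMIModel, metabolome: pd.DataFrame) -> pd.Series:
    """Cohort-wide metBMI from the fitted model (deterministic linear score)."""
    if model.estimator is None:
        raise ValueError("model has no live estimator attached")
    missing = [f for f in model.prefilter_ids if f not in metabolome.columns]
    if missing:
        raise ValueError(f"missing required metabolite(s): {missing}")
    preds = model.estimator.predict(metabolome[model.prefilter_ids])
    return pd.Series(preds, index=metabolome.index, name="metBMI")


# ---------------------------------------------------------------------------
# residual phenotyping
# ---------------------------------------------------------------------------

def classify_residuals(residual, bmi, low: float = -2.5, high: float = 2.5) -> np.ndarray:
    """Group labels from residuals and measured BMI.

    Strict inequalities: residual > high -> HmetBMI, residual < low ->
    LmetBMI; boundary values fall back to the WHO BMI class.
    """
    residual = np.asarray(residual, dtype=float)
    group = who_bmi_class(bmi)
    group[residual > high] = "HmetBMI"
    group[residual < low] = "LmetBMI"
    return group


@dataclass
class ResidualClassification:
    table: pd.DataFrame         # metBMI, residual, group per sample
    thresholds: tuple
    group_sizes: dict
    residual_covariate_corr: dict


def residualize_and_classify(metbmi: pd.Series, cohort: pd.DataFrame,
                             low: float = -2.5, high: float = 2.5) -> ResidualClassification:
    """Residualize metBMI on age, sex and measured BMI over the full cohort
    and classify residual tails.

    Residuals above ``high`` are HmetBMI, below ``low`` are LmetBMI (strict
    inequalities: boundary residuals fall back to the WHO class); all other
    samples keep their WHO BMI class.  Thresholds are in metBMI units
    (kg/m^2).
    """
    cov = cohort.loc[metbmi.index, ["age", "sex", "BMI"]]
    if cov.isna().any().any():
        raise ValueError("age, sex and BMI must be non-missing for residualization")
    design = np.column_stack([np.ones(len(cov)), cov.to_numpy(float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient residualization design (constant covariate?)")
    y = metbmi.to_numpy(float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residual = y - design @ beta
    group = classify_residuals(residual, cov["BMI"], low, high)
    table = pd.DataFrame({"metBMI": y, "residual": residual, "group": group},
                         index=metbmi.index)
    sizes = table["group"].value_counts().to_dict()
    corr = {c: float(np.corrcoef(residual, cov[c].to_numpy(float))[0, 1])
            for c in ("age", "sex", "BMI")}
    return ResidualClassification(table, (low, high), sizes, corr)
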
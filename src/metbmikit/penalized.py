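"""Penalized linear-model machinery shared by the variance-explained and
metBMI stages: lambda grids anchored at the data-derived lambda_max, fast
ridge paths via SVD, lasso paths via coordinate descent (scikit-learn), and
seeded k-fold CV with ties broken toward the larger penalty.

The penalty parametrization follows the elastic-net convention
(1/(2n))||y - Xb||^2 + lambda * P(b) on internally standardized features, so
grids are comparable across sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lasso_path

RIDGE_ANCHOR_FACTOR = 1000.0  # data-scaled anchor: ridge lambda_max = 1000 x lasso lambda_max


@dataclass
class Standardizer:
    mean_: np.ndarray
    sd_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray):
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean, sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


def lasso_lambda_max(Xs: np.ndarray, yc: np.ndarray) -> float:
    """Smallest penalty nulling all lasso coefficients: max |X'y| / n."""
    return float(np.max(np.abs(Xs.T @ yc)) / len(yc))


def make_lambda_grid(Xs, yc, penalty: str, grid_length: int = 100,
                     eps: float = 1e-5, lambda_range=None) -> np.ndarray:
    """Descending log-spaced penalty grid.

    Default is the min-ratio reading: grid_length values from lambda_max down
    to lambda_max * eps, with the ridge anchor scaled up from the lasso
    lambda_max.  Passing ``lambda_range=(lo, hi)`` switches to an absolute
    range instead.
    """
    if lambda_range is not None:
        lo, hi = sorted(float(v) for v in lambda_range)
        return np.logspace(np.log10(hi), np.log10(lo), grid_length)
    lmax = lasso_lambda_max(Xs, yc)
    if lmax <= 0:
        lmax = 1e-3
    if penalty == "ridge":
        lmax *= RIDGE_ANCHOR_FACTOR
    return np.logspace(np.log10(lmax), np.log10(lmax * eps), grid_length)


def ridge_path_coefs(Xs, yc, lambdas) -> np.ndarray:
    """Ridge coefficients for every penalty via one SVD.

    Solves b = argmin (1/(2n))||y - Xb||^2 + (lam/2)||b||^2 for each lam.
    Returns an array of shape (p, len(lambdas)).
    """
    n = len(yc)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc
    lambdas = np.asarray(lambdas, dtype=float)
    # d has shape (rank, n_lambda)
    d = s[:, None] / (s[:, None] ** 2 + n * lambdas[None, :])
    return Vt.T @ (d * uty[:, None])


def path_coefs(Xs, yc, lambdas, penalty: str) -> np.ndarray:
    if penalty == "ridge":
        return ridge_path_coefs(Xs, yc, lambdas)
    if penalty == "lasso":
        # lasso_path requires descending alphas and returns (p, n_alpha)
        _, coefs, _ = lasso_path(Xs, yc, alphas=np.asarray(lambdas, float))
        return coefs
    raise ValueError(f"unknown penalty kind {penalty!r}")


def cv_choose_penalty(X, y, penalty: str, lambdas, k: int = 10, seed=None):
    """Pick the penalty minimizing k-fold CV mean squared error.

    Standardization constants are learned on each training split only.
    Exact ties in CV-MSE are broken toward the larger penalty (the grid is
    descending, so the first minimizer wins).  Returns (chosen_lambda,
    cv_mse_per_lambda).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2 or n < 2 * k:
        raise ValueError(f"cannot run {k}-fold CV with n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    lambdas = np.asarray(lambdas, dtype=float)
    sq_err = np.zeros(lambdas.size)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        std = Standardizer.fit(X[mask])
        Xtr, Xva = std.transform(X[mask]), std.transform(X[~mask])
        ybar = y[mask].mean()
        coefs = path_coefs(Xtr, y[mask] - ybar, lambdas, penalty)
        preds = Xva @ coefs + ybar
        sq_err += ((preds - y[~mask][:, None]) ** 2).sum(axis=0)
    cv_mse = sq_err / n
    best = int(np.argmin(cv_mse))
    return float(lambdas[best]), cv_mse


@dataclass
class PenalizedFit:
    penalty: str
    lam: float
    coef_std: np.ndarray       # coefficients on the standardized feature scale
    intercept_centered: float  # mean of training target
    standardizer: Standardizer

    def predict(self, X) -> np.ndarray:
        Xs = self.standardizer.transform(np.asarray(X, dtype=float))
        return Xs @ self.coef_std + self.intercept_centered


def fit_penalized(X, y, penalty: str, lam: float) -> PenalizedFit:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    ybar = float(y.mean())
    coef = path_coefs(Xs, y - ybar, np.array([lam]), penalty)[:, 0]
    return PenalizedFit(penalty, float(lam), coef, ybar, std)


def holdout_r2(y_true, y_pred) -> float:
    """Hold-out R^2 with the held-out fold's own mean in the denominator.

    Under this convention a predictor emitting the fold's own mean scores
    exactly 0; negative values are reported as-is.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    denom = ((y_true - y_true.mean()) ** 2).sum()
    if denom == 0:
        raise ValueError("hold-out target is constant; R^2 undefined")
    return float(1.0 - ((y_true - y_pred) ** 2).sum() / denom)
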
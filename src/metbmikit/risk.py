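"""Binary-outcome risk models: logistic regressions for BMI-only,
metBMI-only and nested specifications, odds ratios per 1-SD of the
predictor, and likelihood-ratio tests between nested fits.

Fits use iteratively reweighted least squares (statsmodels binomial GLM)
after standardizing the focal predictors to SD 1 on the listwise-complete
analysis sample, so reported odds ratios are per 1-SD increments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._utils import logger

SEPARATION_COEF_LIMIT = 15.0
DEFAULT_COVARIATES = ("age", "sex")
EXTENDED_COVARIATES = ("age", "sex", "whr", "hdl", "ldl", "triglycerides",
                       "systolic_bp", "diastolic_bp", "glucose", "statin_use")


@dataclass
class OutcomeModelResult:
    outcome_name: str
    model_spec: str
    predictors: tuple
    adjustment_set: tuple
    odds_ratios: pd.DataFrame     # per predictor: OR, CI low/high, Wald p (per 1-SD)
    deviance: float
    df_model: int
    n_used: int
    sample_index: tuple = field(repr=False, default=())
    params: dict = field(default_factory=dict)
    data_fingerprint: str = ""


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


def fit_outcome_model(data: pd.DataFrame, outcome: str, predictors,
                      covariates=DEFAULT_COVARIATES,
                      model_spec: str = "custom") -> OutcomeModelResult:
    """Logistic regression of a binary outcome on standardized predictors
    plus covariates, on the listwise-complete sample.

    Predictors are standardized to SD 1 on the analysis sample; covariates
    enter on their raw scale.  Constant covariates are dropped with a
    warning; perfect collinearity or separation raises rather than fitting
    silently.
    """
    predictors = [predictors] if isinstance(predictors, str) else list(predictors)
    covariates = list(covariates)
    cols = [outcome] + predictors + covariates
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns not in data: {missing_cols}")
    frame = data[cols].dropna()
    n = len(frame)
    y = frame[outcome].to_numpy(float)
    classes = set(np.unique(y).tolist())
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1, found {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class on the analysis sample")

    kept_cov = []
    for c in covariates:
        if frame[c].nunique() <= 1:
            logger.warning("fit_outcome_model: constant covariate %r dropped", c)
        else:
            kept_cov.append(c)
    for p in predictors:
        if frame[p].nunique() <= 1:
            raise ValueError(f"constant predictor {p!r}")

    Xp = frame[predictors].to_numpy(float)
    # population SD so the per-1-SD scale is invariant to row duplication
    sds = Xp.std(axis=0, ddof=0)
    Xp = (Xp - Xp.mean(axis=0)) / sds
    Xc = frame[kept_cov].to_numpy(float) if kept_cov else np.empty((n, 0))
    X = np.column_stack([np.ones(n), Xp, Xc])
    names = ["(intercept)"] + predictors + kept_cov
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"collinear design for outcome {outcome!r} (predictors {predictors})")

    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
    coefs = np.asarray(fit.params)
    big = np.abs(coefs[1:1 + len(predictors)]) > SEPARATION_COEF_LIMIT
    if big.any():
        bad = [predictors[i] for i in np.flatnonzero(big)]
        raise ValueError(f"separation detected for predictor(s) {bad} in outcome {outcome!r}")
    ses = np.asarray(fit.bse)
    rows = []
    for i, p in enumerate(predictors, start=1):
        beta, se = coefs[i], ses[i]
        z = beta / se
        rows.append({
            "predictor": p,
            "or_per_sd": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * se)),
            "ci_high": float(np.exp(beta + 1.96 * se)),
            "wald_p": float(2 * sps.norm.sf(abs(z))),
        })
    return OutcomeModelResult(
        outcome_name=outcome, model_spec=model_spec,
        predictors=tuple(predictors), adjustment_set=tuple(kept_cov),
        odds_ratios=pd.DataFrame(rows), deviance=float(fit.deviance),
        df_model=X.shape[1], n_used=n,
        sample_index=tuple(frame.index),
        params={name: float(c) for name, c in zip(names, coefs)},
        data_fingerprint=hashlib.sha256(
            repr(tuple(frame.index)).encode() + y.tobytes()).hexdigest(),
    )


def three_model_comparison(data: pd.DataFrame, outcome: str,
                           bmi_col: str = "BMI", metbmi_col: str = "metBMI",
                           covariates=DEFAULT_COVARIATES):
    """The three specifications compared per outcome: BMI-only, metBMI-only
    and the nested model with both, plus the LRT of nested vs BMI-only.

    All three are fitted on the common listwise-complete sample so deviances
    are comparable.
    """
    frame = data[[outcome, bmi_col, metbmi_col, *covariates]].dropna()
    bmi_only = fit_outcome_model(frame, outcome, [bmi_col], covariates, "bmi_only")
    metbmi_only = fit_outcome_model(frame, outcome, [metbmi_col], covariates, "metbmi_only")
    nested = fit_outcome_model(frame, outcome, [bmi_col, metbmi_col], covariates, "nested")
    lrt = likelihood_ratio_test(full=nested, reduced=bmi_only)
    return {"bmi_only": bmi_only, "metbmi_only": metbmi_only,
            "nested": nested, "lrt_nested_vs_bmi": lrt}


def likelihood_ratio_test(full: OutcomeModelResult,
                          reduced: OutcomeModelResult) -> LRTResult:
    """Deviance-based LRT of nested logistic models on the same samples.

    statistic = deviance(reduced) - deviance(full), df = parameter-count
    difference, p from the chi-square upper tail.
    """
    if full.outcome_name != reduced.outcome_name:
        raise ValueError("models fit different outcomes")
    if (full.sample_index != reduced.sample_index
            or full.data_fingerprint != reduced.data_fingerprint):
        raise ValueError("models fit on different samples; refit on the common sample")
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("reduced predictor set is not a subset of the full set")
    df = full.df_model - reduced.df_model
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced model")
    stat = reduced.deviance - full.deviance
    if stat < -1e-6:
        raise ValueError(f"negative LRT statistic ({stat:.3g}); models not properly nested")
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return LRTResult(float(stat), int(df), p)


def extended_adjustment(data: pd.DataFrame, outcome: str, predictors,
                        covariates=EXTENDED_COVARIATES) -> OutcomeModelResult:
    """Risk model with the traditional-risk-factor adjustment set (WHR,
    lipids, blood pressure, glucose, statin use on top of age and sex).
    The covariate set used is recorded verbatim on the result."""
    present = [c for c in covariates if c in data.columns]
    absent = set(covariates) - set(present)
    if absent:
        logger.warning("extended_adjustment: covariate(s) absent from data: %s", sorted(absent))
    return fit_outcome_model(data, outcome, predictors, present, "extended")
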
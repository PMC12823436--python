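"""Preprocessing transforms for compositional microbiome data and phenotypes.

Implements the standard chain for species/module abundances — prevalence
filtering, total-sum scaling, multiplicative zero replacement, centered
log-ratio (CLR) transform — plus rarefaction-based gene richness,
near-zero-variance screening and the normality-gated log transform used for
phenotype variables.  Functional API operates on :class:`~metbmikit.io.OmicsLayer`
or plain arrays; thin scikit-learn transformer wrappers are provided at the
bottom so the steps compose with sklearn pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import check_rng, logger
from .io import OmicsLayer


# ---------------------------------------------------------------------------
# compositional transforms
# ---------------------------------------------------------------------------

def prevalence_filter(layer: OmicsLayer, min_prevalence: float = 0.05) -> OmicsLayer:
    """Drop features present (value > 0) in fewer than ceil(p * n) samples.

    The boundary is inclusive: a feature present in exactly ceil(p * n)
    samples is retained.  ``min_prevalence=0`` is the identity.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    if np.any(layer.values < 0):
        raise ValueError("prevalence_filter expects nonnegative values")
    need = math.ceil(min_prevalence * layer.n_samples)
    present = (layer.values > 0).sum(axis=0)
    keep = present >= need
    if not keep.any():
        warnings.warn(f"prevalence_filter: no features pass {min_prevalence:.0%} prevalence")
    kept = [f for f, k in zip(layer.feature_ids, keep) if k]
    logger.info("prevalence_filter: kept %d / %d features", len(kept), layer.n_features)
    return OmicsLayer(layer.layer_name, layer.sample_ids, kept,
                      layer.values[:, keep], layer.transform_state)


def tss_normalize(layer: OmicsLayer) -> OmicsLayer:
    """Total-sum scaling: divide each sample's row by its total."""
    v = layer.values
    if np.any(v < 0):
        raise ValueError("tss_normalize expects nonnegative values")
    totals = v.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [layer.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"tss_normalize: zero-sum sample(s) {bad}")
    return OmicsLayer(layer.layer_name, layer.sample_ids, layer.feature_ids,
                      v / totals[:, None], "proportions")


def multiplicative_zero_replacement(layer: OmicsLayer) -> OmicsLayer:
    """Replace zeros in each composition with half the row's smallest nonzero
    proportion, shrinking nonzero parts multiplicatively so rows still sum to 1.
    """
    v = layer.values
    rs = v.sum(axis=1)
    if np.any(np.abs(rs - 1) > 1e-9):
        raise ValueError("multiplicative_zero_replacement expects rows summing to 1 (run TSS first)")
    out = v.copy()
    for i in range(v.shape[0]):
        row = v[i]
        nz = row > 0
        if not nz.any():
            raise ValueError(f"sample {layer.sample_ids[i]!r}: all-zero composition")
        if nz.all():
            continue
        delta = 0.5 * row[nz].min()
        n_zero = int((~nz).sum())
        scale = (1.0 - n_zero * delta) / row[nz].sum()
        out[i, nz] = row[nz] * scale
        out[i, ~nz] = delta
    return OmicsLayer(layer.layer_name, layer.sample_ids, layer.feature_ids, out, "proportions")


def clr_transform(layer: OmicsLayer) -> OmicsLayer:
    """Centered log-ratio: ln(x_ij) minus the mean log of sample i's row."""
    v = layer.values
    if np.any(v <= 0):
        i, j = np.argwhere(v <= 0)[0]
        raise ValueError(
            f"clr_transform: nonpositive entry at sample {layer.sample_ids[i]!r}, "
            f"feature {layer.feature_ids[j]!r}; apply multiplicative_zero_replacement first"
        )
    logv = np.log(v)
    clr = logv - logv.mean(axis=1, keepdims=True)
    return OmicsLayer(layer.layer_name, layer.sample_ids, layer.feature_ids, clr, "clr")


def counts_to_clr(layer: OmicsLayer, min_prevalence: float = 0.05) -> OmicsLayer:
    """Convenience chain: prevalence filter -> TSS -> zero replacement -> CLR."""
    return clr_transform(multiplicative_zero_replacement(
        tss_normalize(prevalence_filter(layer, min_prevalence))))


# ---------------------------------------------------------------------------
# phenotype screening
# ---------------------------------------------------------------------------

def near_zero_variance_flags(table: pd.DataFrame,
                             freq_ratio: float = 19.0,
                             unique_fraction: float = 0.10) -> list:
    """Flag columns with degenerate distributions.

    A column is flagged when the frequency ratio of its most common to
    second-most-common value is >= ``freq_ratio`` (default 19 = 95/5) AND the
    fraction of distinct values is <= ``unique_fraction``.  Constant columns
    are always flagged.
    """
    flagged = []
    n = len(table)
    for col in table.columns:
        vals = table[col].dropna()
        counts = vals.value_counts()
        if len(counts) <= 1:
            flagged.append(col)
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        uniq = len(counts) / n
        if ratio >= freq_ratio and uniq <= unique_fraction:
            flagged.append(col)
    return flagged


def _anderson_darling_p(x: np.ndarray) -> float:
    """Anderson-Darling normality test p-value (estimated mean/sd case).

    scipy reports only the statistic and critical values; the p-value uses the
    standard small-sample correction AA = A^2 (1 + 0.75/n + 2.25/n^2) and the
    piecewise exponential approximation of Stephens/D'Agostino.
    """
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    logcdf = stats.norm.logcdf(z)
    logsf = stats.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (logcdf + logsf[::-1]))
    aa = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if aa < 0.2:
        p = 1 - math.exp(-13.436 + 101.14 * aa - 223.73 * aa**2)
    elif aa < 0.34:
        p = 1 - math.exp(-8.318 + 42.796 * aa - 59.938 * aa**2)
    elif aa < 0.6:
        p = math.exp(0.9177 - 4.279 * aa - 1.38 * aa**2)
    elif aa < 10:
        p = math.exp(1.2937 - 5.709 * aa + 0.0186 * aa**2)
    else:
        p = 3.7e-24
    return float(min(max(p, 0.0), 1.0))


@dataclass
class LogTransformFlag:
    transformed: bool
    ad_p: float
    offset: float
    note: str = ""


def normality_gated_log(x, alpha: float = 0.05):
    """Log-transform a variable only if it fails an Anderson-Darling
    normality test at ``alpha``.

    Non-normal variables return ln(x + offset) with offset 0 when min > 0,
    else (1 - min) so the smallest value maps to ln(1) = 0.  Returns the
    (possibly transformed) values and a flag recording the decision.
    """
    arr = np.asarray(x, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 8:
        raise ValueError("normality_gated_log needs >= 8 non-missing values")
    if np.ptp(finite) == 0:
        return arr, LogTransformFlag(False, 1.0, 0.0, note="constant input, returned unchanged")
    p = _anderson_darling_p(finite)
    if p >= alpha:
        return arr, LogTransformFlag(False, p, 0.0)
    mn = finite.min()
    offset = 0.0 if mn > 0 else 1.0 - mn
    return np.log(arr + offset), LogTransformFlag(True, p, offset)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefied_gene_richness(gene_counts: OmicsLayer, depth: int,
                           n_repeats: int = 50, seed=None) -> pd.DataFrame:
    """Gene richness after rarefying each sample to a fixed read depth.

    Each repeat draws exactly ``depth`` reads without replacement
    (multivariate hypergeometric); richness is the number of genes with at
    least one read.  Returns per-sample mean and SD over repeats; samples
    with fewer than ``depth`` total reads are reported missing (NaN).
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = check_rng(seed)
    counts = np.asarray(np.round(gene_counts.values), dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("gene counts must be nonnegative")
    means = np.full(counts.shape[0], np.nan)
    sds = np.full(counts.shape[0], np.nan)
    for i, row in enumerate(counts):
        total = int(row.sum())
        if total < depth:
            logger.info("rarefied_gene_richness: sample %s has %d < depth %d reads; reported missing",
                        gene_counts.sample_ids[i], total, depth)
            continue
        if total == depth:
            means[i], sds[i] = float((row > 0).sum()), 0.0
            continue
        rich = np.empty(n_repeats)
        for r in range(n_repeats):
            sub = rng.multivariate_hypergeometric(row, depth)
            rich[r] = (sub > 0).sum()
        means[i], sds[i] = rich.mean(), rich.std(ddof=0)
    return pd.DataFrame({"richness_mean": means, "richness_sd": sds},
                        index=gene_counts.sample_ids)


# ---------------------------------------------------------------------------
# sklearn transformer wrappers (arrays / DataFrames in, arrays out)
# ---------------------------------------------------------------------------

class _LayerOpMixin:
    def _to_layer(self, X) -> OmicsLayer:
        if isinstance(X, OmicsLayer):
            return X
        if isinstance(X, pd.DataFrame):
            return OmicsLayer.from_frame(X, "X", "raw")
        X = np.asarray(X, dtype=float)
        return OmicsLayer("X", [str(i) for i in range(X.shape[0])],
                          [str(j) for j in range(X.shape[1])], X, "raw")


class CLRTransformer(TransformerMixin, BaseEstimator, _LayerOpMixin):
    """TSS + multiplicative zero replacement + CLR, as an sklearn transformer."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        layer = self._to_layer(X)
        return clr_transform(multiplicative_zero_replacement(tss_normalize(layer))).values


class PrevalenceFilter(TransformerMixin, BaseEstimator, _LayerOpMixin):
    """Stateful prevalence filter: support learned at fit time."""

    def __init__(self, min_prevalence: float = 0.05):
        self.min_prevalence = min_prevalence

    def fit(self, X, y=None):
        layer = self._to_layer(X)
        need = math.ceil(self.min_prevalence * layer.n_samples)
        self.support_ = (layer.values > 0).sum(axis=0) >= need
        self.n_features_in_ = layer.n_features
        return self

    def transform(self, X):
        return self._to_layer(X).values[:, self.support_]

    def get_support(self):
        return self.support_


class NearZeroVarianceFilter(TransformerMixin, BaseEstimator):
    """Drop near-zero-variance columns (frequency-ratio and unique-fraction rule)."""

    def __init__(self, freq_ratio: float = 19.0, unique_fraction: float = 0.10):
        self.freq_ratio = freq_ratio
        self.unique_fraction = unique_fraction

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        flagged = set(near_zero_variance_flags(df, self.freq_ratio, self.unique_fraction))
        self.support_ = np.array([c not in flagged for c in df.columns])
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X):
        arr = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        return arr[:, self.support_]
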
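"""Tabular I/O for omics layers and the cohort table.

Layers are rectangular TSV files with samples as rows, a header row and the
sample identifier in the first column.  In memory a layer is an
:class:`OmicsLayer`: a named sample-by-feature matrix carrying a
transform-state tag so downstream stages can assert they receive data on the
scale they expect (raw counts, proportions, CLR, log intensities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import logger

TRANSFORM_STATES = ("counts", "proportions", "clr", "log", "raw")


@dataclass
class OmicsLayer:
    """A named sample x feature matrix with a transform-state tag."""

    layer_name: str
    sample_ids: list
    feature_ids: list
    values: np.ndarray
    transform_state: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(
                f"unknown transform_state {self.transform_state!r}; "
                f"expected one of {TRANSFORM_STATES}"
            )
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"layer {self.layer_name!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for kind, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"layer {self.layer_name!r}: duplicate {kind} id(s) {dupes}")
        if self.transform_state == "counts":
            if np.any(self.values < 0) or not np.allclose(self.values, np.round(self.values)):
                raise ValueError(
                    f"layer {self.layer_name!r}: counts state requires nonnegative integers"
                )
        if self.transform_state == "clr":
            rs = self.values.sum(axis=1)
            if np.any(np.abs(rs) > 1e-9):
                bad = int(np.argmax(np.abs(rs)))
                raise ValueError(
                    f"layer {self.layer_name!r}: clr state requires zero row sums; "
                    f"sample {self.sample_ids[bad]!r} sums to {rs[bad]:.3g}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer_name: str, transform_state: str = "raw"):
        return cls(layer_name, list(df.index), list(df.columns), df.to_numpy(float), transform_state)

    def select_features(self, keep) -> "OmicsLayer":
        idx = [self.feature_ids.index(f) for f in keep]
        return OmicsLayer(
            self.layer_name, self.sample_ids, [self.feature_ids[i] for i in idx],
            self.values[:, idx], self.transform_state,
        )


def read_layer(path, layer_name: str, transform_state: str = "raw") -> OmicsLayer:
    """Read a sample-by-feature TSV into an :class:`OmicsLayer`.

    Errors name the offending row/column: duplicate ids, ragged rows and
    non-numeric cells are all rejected rather than coerced.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature id(s) {dupes}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing/ragged cell at sample {df.index[r]!r}, column {df.columns[c]!r}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            r = int(np.argmax(bad.isna().to_numpy()))
            raise ValueError(
                f"{path}: non-numeric cell at sample {df.index[r]!r}, column {col!r}: "
                f"{df.iloc[r, j]!r}"
            ) from None
    return OmicsLayer(layer_name, list(df.index), list(df.columns), values, transform_state)


def write_layer(layer: OmicsLayer, path) -> None:
    """Write a layer as TSV at full float precision (round-trip exact)."""
    df = layer.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=None)


def read_cohort(path) -> pd.DataFrame:
    """Read the per-sample cohort table (covariates, outcomes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    if "BMI" in df.columns and (df["BMI"].dropna() <= 0).any():
        raise ValueError("cohort table: BMI must be positive")
    if "sex" in df.columns:
        vals = set(df["sex"].dropna().unique().tolist())
        if not vals <= {0, 1, 0.0, 1.0}:
            raise ValueError(f"cohort table: sex must be coded 0/1, found {sorted(vals)}")


def write_cohort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    logger.info("wrote cohort table with %d samples to %s", len(out), path)
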
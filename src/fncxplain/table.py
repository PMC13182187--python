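"""Labeled feature tables: the tabular interchange object of the pipeline.

A table is a pandas DataFrame with one row per subject and columns
``subject_id``, ``label`` (exactly two classes), optional covariate columns
(e.g. ``age``, ``sex``, ``site``) and feature columns ``f0000..fNNNN`` in the
canonical upper-triangle order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_RE = re.compile(r"^f\d{4,}$")
RESERVED = ("subject_id", "label")


class TableSchemaError(ValueError):
    """A feature table violates the expected schema."""


@dataclass
class LabeledFeatureTable:
    """Subjects x features with a binary label and optional covariates."""

    frame: pd.DataFrame
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.frame
        for col in RESERVED:
            if col not in df.columns:
                raise TableSchemaError(f"missing required column {col!r}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise TableSchemaError(f"duplicate subject ids: {dupes[:5]}")
        labels = pd.unique(df["label"])
        if len(labels) != 2:
            raise TableSchemaError(f"expected exactly two label values, found {list(labels)}")
        feats = self.feature_cols
        if not feats:
            raise TableSchemaError("no feature columns (f0000-style) found")
        block = df[feats]
        if not all(np.issubdtype(dt, np.number) for dt in block.dtypes):
            bad = [c for c, dt in block.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise TableSchemaError(f"non-numeric feature columns: {bad[:5]}")
        if block.isna().any().any():
            rows = np.flatnonzero(block.isna().any(axis=1))
            raise TableSchemaError(f"missing feature values in rows {rows[:5].tolist()}")
        missing_cov = [c for c in self.covariate_cols if c not in df.columns]
        if missing_cov:
            raise TableSchemaError(f"declared covariate columns absent: {missing_cov}")

    @property
    def feature_cols(self) -> list[str]:
        return [c for c in self.frame.columns if FEATURE_RE.match(str(c))]

    @property
    def n_features(self) -> int:
        return len(self.feature_cols)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Labels as 0/1; the positive class is the lexicographically first label."""
        classes = self.classes
        return (self.frame["label"].to_numpy() == classes[0]).astype(int)

    @property
    def classes(self) -> list:
        return sorted(pd.unique(self.frame["label"]), key=str)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame[self.covariate_cols]

    def class_counts(self) -> dict:
        return self.frame["label"].value_counts().to_dict()

    def with_features(self, X: np.ndarray) -> "LabeledFeatureTable":
        """Copy of the table with the feature block replaced (same columns)."""
        if X.shape != (len(self.frame), self.n_features):
            raise ValueError(f"feature block shape {X.shape} does not match table")
        df = self.frame.copy()
        df[self.feature_cols] = X
        return LabeledFeatureTable(df, list(self.covariate_cols))
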
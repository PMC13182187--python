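"""File I/O: feature tables, time courses, manifests.

All on-disk formats are plain text — TSV for tables, JSON for summaries and
model dumps, YAML for configuration — so every artifact can be inspected
and re-plotted without this package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fnc import TimeCourseSet, compute_fnc, vectorize, feature_names
from .table import FEATURE_RE, LabeledFeatureTable, TableSchemaError


def read_feature_table(path: str | Path, covariate_cols: list[str] | None = None) -> LabeledFeatureTable:
    """Read a subjects-x-features TSV/CSV into a validated table.

    Columns are ``subject_id``, ``label``, any covariates, and features named
    ``f0000``-style.  Undeclared non-feature, non-reserved columns are taken
    to be covariates.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "label" not in df.columns or "subject_id" not in df.columns:
        raise TableSchemaError(
            f"{path.name}: header must contain 'subject_id' and 'label'; found {list(df.columns)[:6]}"
        )
    feature_cols = [c for c in df.columns if FEATURE_RE.match(str(c))]
    for c in feature_cols:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()].tolist()
            raise TableSchemaError(f"{path.name}: non-numeric values in column {c} at rows {bad[:5]}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns
                          if c not in ("subject_id", "label") and c not in feature_cols]
    return LabeledFeatureTable(df, covariate_cols)


def write_feature_table(table: LabeledFeatureTable, path: str | Path) -> None:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    table.frame.to_csv(path, sep=sep, index=False)


def read_timecourses(path: str | Path, subject_id: str | None = None) -> TimeCourseSet:
    """One subject's components-x-timepoints matrix from a delimited file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    else:  # any whitespace
        values = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)
    return TimeCourseSet(subject_id=subject_id or path.stem, values=values)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Subject manifest TSV: subject_id, path, label, plus covariates."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "path", "label"):
        if col not in df.columns:
            raise TableSchemaError(f"{path.name}: manifest must contain column {col!r}")
    return df


def feature_table_from_timecourses(manifest: pd.DataFrame, base_dir: str | Path = ".") -> LabeledFeatureTable:
    """Compute the FNC feature table for every subject in a manifest."""
    base = Path(base_dir)
    rows = []
    n_components = None
    for rec in manifest.to_dict("records"):
        tc = read_timecourses(base / rec["path"], subject_id=str(rec["subject_id"]))
        if n_components is None:
            n_components = tc.n_components
        elif tc.n_components != n_components:
            raise ValueError(
                f"subject {rec['subject_id']}: {tc.n_components} components, expected {n_components}"
            )
        vec = vectorize(compute_fnc(tc))
        row = {k: v for k, v in rec.items() if k != "path"}
        row.update(zip(feature_names(n_components), vec))
        rows.append(row)
    df = pd.DataFrame(rows)
    covs = [c for c in manifest.columns if c not in ("subject_id", "path", "label")]
    return LabeledFeatureTable(df, covs)
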
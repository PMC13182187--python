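"""Leakage-free removal of covariate effects from features.

Confounds such as age, sex and acquisition site are regressed out of every
feature with ordinary least squares fitted on *training rows only*; the
fitted coefficients are then applied to held-out rows.  Fitting and applying
are separate steps on purpose: residualizing train and test jointly leaks
the test covariate distribution into the training features.

Categorical covariates (sex, site) are expanded to indicator columns with
the first level dropped; continuous covariates enter as-is.  A category
level never seen during fitting is an error — silently encoding it as
all-zeros would alias it onto the reference level and bias attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class UnseenLevelError(ValueError):
    """A categorical covariate level absent from the training design."""


class RankDeficientDesignError(ValueError):
    """The confound design matrix has collinear columns."""


def _is_categorical(col: pd.Series) -> bool:
    return not np.issubdtype(col.dtype, np.number)


@dataclass
class ConfoundModel:
    """Per-feature OLS coefficients over a fixed covariate design."""

    covariate_cols: list[str]
    levels: dict[str, list]          # fitted category levels per categorical col
    design_cols: list[str]           # expanded design column order (after intercept)
    coef: np.ndarray                 # (n_design + 1, n_features); row 0 = intercept
    fitted_on: list = field(default_factory=list)

    def design_matrix(self, covariates: pd.DataFrame) -> np.ndarray:
        """Expand covariates to the fitted design (without intercept)."""
        missing = [c for c in self.covariate_cols if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariate columns missing at apply time: {missing}")
        blocks: list[np.ndarray] = []
        for c in self.covariate_cols:
            col = covariates[c]
            if c in self.levels:
                fitted = self.levels[c]
                unseen = sorted(set(col.astype(object)) - set(fitted))
                if unseen:
                    raise UnseenLevelError(
                        f"covariate {c!r} has level(s) {unseen} never seen during fitting"
                    )
                # first fitted level is the dropped reference
                for lev in fitted[1:]:
                    blocks.append((col.to_numpy(dtype=object) == lev).astype(float))
            else:
                blocks.append(col.to_numpy(dtype=float))
        if not blocks:
            return np.empty((len(covariates), 0))
        return np.column_stack(blocks)


def fit_residualizer(
    features: np.ndarray, covariates: pd.DataFrame, covariate_cols: list[str] | None = None,
    row_ids: list | None = None,
) -> ConfoundModel:
    """OLS fit of every feature on the covariate design (training rows only)."""
    if covariate_cols is None:
        covariate_cols = list(covariates.columns)
    features = np.asarray(features, dtype=float)
    if covariates[covariate_cols].isna().any().any():
        raise ValueError("missing covariate values in training rows")

    levels: dict[str, list] = {}
    design_cols: list[str] = []
    for c in covariate_cols:
        if _is_categorical(covariates[c]):
            levs = sorted(pd.unique(covariates[c]).tolist(), key=str)
            levels[c] = levs
            design_cols += [f"{c}[{lev}]" for lev in levs[1:]]
        else:
            design_cols.append(c)

    model = ConfoundModel(
        covariate_cols=list(covariate_cols), levels=levels, design_cols=design_cols,
        coef=np.empty(0), fitted_on=list(row_ids) if row_ids is not None else [],
    )
    D = model.design_matrix(covariates)
    n, p = D.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} training rows for {p} design columns, got {n}")
    A = np.column_stack([np.ones(n), D])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        from scipy.linalg import qr
        _, _, piv = qr(A, pivoting=True)
        redundant = [(["intercept"] + design_cols)[i] for i in sorted(piv[rank:])]
        raise RankDeficientDesignError(
            f"confound design is rank deficient; collinear column(s): {redundant}"
        )
    coef, *_ = np.linalg.lstsq(A, features, rcond=None)
    model.coef = coef
    return model


def apply_residualizer(
    model: ConfoundModel, features: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """Subtract the covariate effect predicted by a fitted model.

    Never refits: held-out rows are residualized with training coefficients.
    """
    features = np.asarray(features, dtype=float)
    D = model.design_matrix(covariates)
    A = np.column_stack([np.ones(len(D)), D])
    if model.coef.size == 0:
        raise ValueError("model has not been fitted")
    if features.shape[1] != model.coef.shape[1]:
        raise ValueError(
            f"feature count {features.shape[1]} does not match fitted model ({model.coef.shape[1]})"
        )
    return features - A @ model.coef
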
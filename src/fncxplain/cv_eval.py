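"""Repeated stratified cross-validation, metrics, and model comparison.

The evaluation protocol: repeated stratified k-fold cross-validation
(default 10 folds), each repetition with a fresh seeded fold plan.  Within
every fold, confounds are regressed out with coefficients fitted on the
training rows only, the model is fitted on the training rows, scored on the
held-out rows, and the held-out rows are attributed with the tree-path
Shapley algorithm.  Nothing from a test fold — rows, labels or covariate
distribution — ever reaches a fitting step.

Metrics are the standard confusion-matrix set (accuracy, sensitivity,
specificity, F1) plus AUC computed as the Mann-Whitney rank statistic.
Cross-model comparison uses the corrected resampled t-test, which inflates
the paired-difference variance by ``1/n + n_test/n_train`` to account for
the overlap of training sets across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .confounds import apply_residualizer, fit_residualizer
from .shapley import tree_shapley
from .table import LabeledFeatureTable


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of rows into k folds."""

    k: int
    assignments: np.ndarray  # fold id per row
    seed: int

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Seed-deterministic stratified k-fold assignment.

    Every class must have at least k members; per-fold class proportions
    are within one sample of the global proportions.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if (counts < k).any():
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV; counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        )


@dataclass(frozen=True)
class MetricSet:
    """Classification metrics; an undefined ratio is reported as NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1, "auc": self.auc}


def metrics(counts: ConfusionCounts, scores: np.ndarray | None = None,
            labels: np.ndarray | None = None) -> MetricSet:
    """Confusion-matrix metrics plus rank-statistic AUC.

    accuracy = (TP+TN)/(TP+FN+TN+FP); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); F1 = 2TP/(2TP+FP+FN).  AUC is computed from
    ``scores`` against ``labels`` as the Mann-Whitney U statistic (identical
    to the trapezoidal ROC area with midrank tie handling); it is NaN when
    either class is empty or no scores are supplied.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if counts.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    auc = float("nan")
    if scores is not None and labels is not None:
        labels = np.asarray(labels).astype(int)
        if len(np.unique(labels)) == 2:
            auc = float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
    return MetricSet(
        accuracy=(tp + tn) / counts.total,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        f1=ratio(2 * tp, 2 * tp + fp + fn),
        auc=auc,
    )


def corrected_paired_test(metrics_a: np.ndarray, metrics_b: np.ndarray,
                          n_train: int, n_test: int) -> tuple[float, float]:
    """Corrected resampled paired t-test over per-fold metrics.

    The naive paired t-test is anti-conservative under cross-validation
    because training sets overlap; the correction replaces the variance
    factor 1/n with ``1/n + n_test/n_train``.  Returns (t, two-sided p).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length per-fold metric vectors (length >= 2)")
    d = a - b
    n = len(d)
    var = d.var(ddof=1)
    mean = d.mean()
    if var == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / np.sqrt((1.0 / n + n_test / n_train) * var)
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class FoldAttributions:
    """Pooled held-out-row attributions of one model across all folds."""

    subject_ids: list = field(default_factory=list)
    iterations: list = field(default_factory=list)
    X: list = field(default_factory=list)       # residualized feature values
    phi: list = field(default_factory=list)
    base_values: list = field(default_factory=list)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        return np.vstack(self.X), np.vstack(self.phi)


@dataclass
class CVResult:
    metrics: pd.DataFrame                       # iteration, fold, model, n_train, n_test, metrics...
    attributions: dict[str, FoldAttributions]
    fold_plans: list[FoldPlan]

    def mean_metric(self, model: str, metric: str = "accuracy") -> float:
        sub = self.metrics[self.metrics["model"] == model]
        return float(sub[metric].mean())

    def summary(self, by_iteration: bool = False) -> pd.DataFrame:
        """Mean +/- SD per model, over all folds or per iteration."""
        cols = ["accuracy", "sensitivity", "specificity", "f1", "auc"]
        keys = ["model", "iteration"] if by_iteration else ["model"]
        return self.metrics.groupby(keys)[cols].agg(["mean", "std"])


def run_repeated_cv(
    table: LabeledFeatureTable,
    model_factories: dict[str, object],
    *,
    k: int = 10,
    iterations: int = 1,
    confound_cols: list[str] | None = None,
    seed: int = 0,
    attribute: bool = True,
) -> CVResult:
    """The full leakage-free protocol: residualize, fit, score, attribute.

    ``model_factories`` maps model name to a zero-argument callable
    returning a fresh unfitted model (see :mod:`fncxplain.models`).  All
    randomness — fold plans and every model fit — derives from ``seed`` via
    named substreams, so a rerun reproduces every output exactly.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X_all = table.X
    y_all = table.y
    ids = table.frame["subject_id"].to_numpy()
    confound_cols = confound_cols or []
    root = np.random.SeedSequence(seed)
    fold_seeds, fit_seeds = root.spawn(2)
    fold_rng = np.random.default_rng(fold_seeds)
    fit_rng = np.random.default_rng(fit_seeds)

    rows = []
    attributions = {name: FoldAttributions() for name in model_factories}
    fold_plans = []
    for it in range(iterations):
        plan = make_folds(y_all, k, seed=int(fold_rng.integers(2**31)))
        fold_plans.append(plan)
        for fold in range(k):
            tr, te = plan.train_rows(fold), plan.test_rows(fold)
            X_tr, X_te = X_all[tr], X_all[te]
            if confound_cols:
                try:
                    cm = fit_residualizer(X_tr, table.frame.iloc[tr][confound_cols],
                                          confound_cols, row_ids=list(ids[tr]))
                    X_tr = apply_residualizer(cm, X_tr, table.frame.iloc[tr][confound_cols])
                    X_te = apply_residualizer(cm, X_te, table.frame.iloc[te][confound_cols])
                except Exception as exc:
                    raise RuntimeError(
                        f"[confounds] iteration {it} fold {fold}: {exc}") from exc
            for name, factory in model_factories.items():
                try:
                    model = factory().fit(X_tr, y_all[tr], seed=int(fit_rng.integers(2**31)))
                    scores = np.asarray(model.predict_proba(X_te), dtype=float)
                except Exception as exc:
                    raise RuntimeError(f"[fit:{name}] iteration {it} fold {fold}: {exc}") from exc
                preds = (scores >= 0.5).astype(int)
                ms = metrics(ConfusionCounts.from_predictions(y_all[te], preds),
                             scores, y_all[te])
                rows.append({"iteration": it, "fold": fold, "model": name,
                             "n_train": len(tr), "n_test": len(te), **ms.as_dict()})
                if attribute:
                    try:
                        attrs = tree_shapley(model.ensemble(), X_te)
                    except Exception as exc:
                        raise RuntimeError(
                            f"[attribute:{name}] iteration {it} fold {fold}: {exc}") from exc
                    acc = attributions[name]
                    acc.subject_ids.extend(ids[te])
                    acc.iterations.extend([it] * len(te))
                    acc.X.append(X_te)
                    acc.phi.append(np.vstack([a.phi for a in attrs]))
                    acc.base_values.extend(a.base_value for a in attrs)
    return CVResult(metrics=pd.DataFrame(rows), attributions=attributions,
                    fold_plans=fold_plans)
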
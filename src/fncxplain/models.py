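"""Model registry: the three classifier architectures of the pipeline.

Every model satisfies a small protocol — ``fit(X, y, seed)``,
``predict_proba(X)`` and ``ensemble()`` — where ``ensemble()`` exports the
fitted trees to the flat JSON tree schema so the tree-path Shapley
algorithm can attribute any of them uniformly:

* ``forest`` — the in-repo bagged voting forest;
* ``gbm``    — the in-repo sequential gradient-boosted trees;
* ``ext``    — extremely randomized trees via scikit-learn, filling the
  third architecture slot through the pluggable interface (the study's
  third library model adds categorical-feature machinery that is inert on
  all-continuous connectivity features).

Any other scikit-learn tree model convertible by
:func:`fncxplain.trees.from_sklearn` can be plugged in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from . import trees as _trees
from .trees import TreeEnsemble, from_sklearn


class FittedModel(Protocol):
    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...
    def ensemble(self) -> TreeEnsemble: ...


@dataclass
class ForestModel:
    """Bagged voting forest (in-repo CART trees, average-probability vote)."""

    n_trees: int = 50
    max_depth: int = 90
    min_samples_split: int = 5
    min_samples_leaf: int = 2
    max_features: int | str | None = "sqrt"
    _fitted: TreeEnsemble | None = field(default=None, repr=False)

    def fit(self, X, y, seed: int = 0) -> "ForestModel":
        self._fitted = _trees.fit_forest(
            X, y, n_trees=self.n_trees, max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features, seed=seed,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.ensemble().predict_proba(X)

    def ensemble(self) -> TreeEnsemble:
        if self._fitted is None:
            raise RuntimeError("model has not been fitted")
        return self._fitted


@dataclass
class GBMModel:
    """Sequential gradient-boosted trees with logistic loss (in-repo)."""

    n_rounds: int = 30
    learning_rate: float = 0.1
    max_depth: int = 3
    min_samples_split: int = 5
    min_samples_leaf: int = 2
    colsample: float = 0.25
    _fitted: TreeEnsemble | None = field(default=None, repr=False)

    def fit(self, X, y, seed: int = 0) -> "GBMModel":
        self._fitted = _trees.fit_gbm(
            X, y, n_rounds=self.n_rounds, learning_rate=self.learning_rate,
            max_depth=self.max_depth, min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf, colsample=self.colsample,
            seed=seed,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.ensemble().predict_proba(X)

    def ensemble(self) -> TreeEnsemble:
        if self._fitted is None:
            raise RuntimeError("model has not been fitted")
        return self._fitted


@dataclass
class SklearnTreeModel:
    """Adapter plugging a scikit-learn tree classifier into the pipeline.

    The estimator is cloned per fit; after fitting it is exported to the
    JSON tree schema for attribution.
    """

    estimator_factory: object = None  # callable(seed) -> unfitted estimator
    _fitted_est: object = field(default=None, repr=False)
    _exported: TreeEnsemble | None = field(default=None, repr=False)

    def fit(self, X, y, seed: int = 0) -> "SklearnTreeModel":
        est = self.estimator_factory(seed)
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        self._fitted_est = est
        self._exported = from_sklearn(est)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self._fitted_est is None:
            raise RuntimeError("model has not been fitted")
        return self._fitted_est.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def ensemble(self) -> TreeEnsemble:
        if self._exported is None:
            raise RuntimeError("model has not been fitted")
        return self._exported


def _extra_trees_factory(seed: int):
    from sklearn.ensemble import ExtraTreesClassifier
    return ExtraTreesClassifier(
        n_estimators=100, max_depth=None, min_samples_split=5,
        min_samples_leaf=2, random_state=seed,
    )


def build_model(name: str, **params):
    """Construct a fresh model by registry name (``forest``/``gbm``/``ext``)."""
    if name == "forest":
        return ForestModel(**params)
    if name == "gbm":
        return GBMModel(**params)
    if name == "ext":
        return SklearnTreeModel(estimator_factory=params.pop("estimator_factory", _extra_trees_factory))
    raise KeyError(f"unknown model {name!r}; registry has forest, gbm, ext")


#: Cross-validated protocol defaults of the clinical preset: 200-tree forest
#: with deep trees, as used for the multi-site case-control analysis.
FBIRN_FOREST = dict(n_trees=200, max_depth=90, min_samples_split=5, min_samples_leaf=2)
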
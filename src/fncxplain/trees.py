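"""Binary-split tree learners: CART, bagged voting forest, gradient boosting.

All three model families used by the pipeline reduce to ensembles of
axis-aligned binary split trees, which is exactly the structure the
tree-path Shapley algorithm consumes.  Trees are stored in flat arrays
(feature, threshold, children, leaf value, cover) where *cover* is the
number of training rows that reached each node — the weighting the
attribution algorithm uses to marginalize absent features.

Conventions, fixed for reproducibility:

* split rule is ``x[feature] <= threshold`` goes left;
* candidate thresholds are midpoints between consecutive distinct sorted
  values;
* split quality is Gini impurity for classification and squared error for
  the regression trees inside boosting;
* ties in gain are broken toward the lowest feature index, then the lowest
  threshold.

Boosted leaf values carry the learning rate folded in, so an additive
ensemble's margin is always ``base_margin + sum(tree outputs)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

LEAF = -1
_EPS = 1e-12


@dataclass
class Tree:
    """One binary split tree in flat-array form."""

    feature: np.ndarray    # split feature per node; -1 at leaves
    threshold: np.ndarray  # split threshold per node; nan at leaves
    left: np.ndarray       # child node ids; -1 at leaves
    right: np.ndarray
    value: np.ndarray      # leaf value (class-1 probability or additive margin)
    cover: np.ndarray      # training rows reaching each node

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def is_leaf(self, node: int) -> bool:
        return self.feature[node] == LEAF

    def max_depth(self) -> int:
        depth = np.zeros(self.n_nodes, dtype=int)
        for node in range(self.n_nodes):
            if not self.is_leaf(node):
                depth[self.left[node]] = depth[node] + 1
                depth[self.right[node]] = depth[node] + 1
        return int(depth.max()) if self.n_nodes else 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf value for each row of ``X`` (vectorized descent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(len(X), dtype=np.int64)
        active = ~self.is_leaf_mask()[node]
        while active.any():
            f = self.feature[node[active]]
            t = self.threshold[node[active]]
            go_left = X[active, f] <= t
            nxt = np.where(go_left, self.left[node[active]], self.right[node[active]])
            node[active] = nxt
            active = ~self.is_leaf_mask()[node]
        return self.value[node]

    def is_leaf_mask(self) -> np.ndarray:
        return self.feature == LEAF

    def to_dict(self) -> dict:
        nodes = []
        for i in range(self.n_nodes):
            if self.is_leaf(i):
                nodes.append({"leaf_value": float(self.value[i]), "cover": float(self.cover[i])})
            else:
                nodes.append({
                    "feature_index": int(self.feature[i]),
                    "threshold": float(self.threshold[i]),
                    "left": int(self.left[i]),
                    "right": int(self.right[i]),
                    "cover": float(self.cover[i]),
                })
        return {"nodes": nodes}

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        nodes = d["nodes"]
        n = len(nodes)
        feature = np.full(n, LEAF, dtype=np.int64)
        threshold = np.full(n, np.nan)
        left = np.full(n, LEAF, dtype=np.int64)
        right = np.full(n, LEAF, dtype=np.int64)
        value = np.zeros(n)
        cover = np.zeros(n)
        for i, node in enumerate(nodes):
            cover[i] = node.get("cover", np.nan)
            if "feature_index" in node:
                feature[i] = node["feature_index"]
                threshold[i] = node["threshold"]
                left[i] = node["left"]
                right[i] = node["right"]
            else:
                value[i] = node["leaf_value"]
        if np.isnan(cover).any():
            raise ValueError("tree nodes are missing cover counts")
        return cls(feature, threshold, left, right, value, cover)


@dataclass
class TreeEnsemble:
    """Ordered tree list with a fixed combine rule.

    ``combine`` is ``"average_probability"`` (voting forest: prediction is
    the mean of member-tree class-1 probabilities) or ``"additive_margin"``
    (boosting: prediction is the logistic link applied to
    ``base_margin + sum of tree outputs``).
    """

    trees: list[Tree]
    combine: str
    n_features: int
    base_margin: float = 0.0
    learning_rate: float | None = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("ensemble must contain at least one tree")
        if self.combine not in ("average_probability", "additive_margin"):
            raise ValueError(f"unknown combine rule {self.combine!r}")

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return X

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        """Additive margin (boosting) or mean probability (forest)."""
        X = self._check(X)
        out = np.sum([t.predict(X) for t in self.trees], axis=0)
        if self.combine == "average_probability":
            return out / len(self.trees)
        return self.base_margin + out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability per row."""
        m = self.predict_margin(X)
        if self.combine == "average_probability":
            return m
        return _sigmoid(m)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "combine": self.combine,
            "n_features": self.n_features,
            "base_margin": self.base_margin,
            "learning_rate": self.learning_rate,
            "metadata": self.metadata,
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TreeEnsemble":
        text = Path(source).read_text() if Path(str(source)[:200]).exists() else str(source)
        payload = json.loads(text)
        return cls(
            trees=[Tree.from_dict(t) for t in payload["trees"]],
            combine=payload["combine"],
            n_features=payload["n_features"],
            base_margin=payload.get("base_margin", 0.0),
            learning_rate=payload.get("learning_rate"),
            metadata=payload.get("metadata", {}),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# CART construction


def _best_split(X: np.ndarray, y: np.ndarray, feat_idx: np.ndarray,
                min_leaf: int, task: str) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) at a node, or None if unsplittable.

    Fully vectorized: sorts each candidate feature column once and evaluates
    every midpoint threshold from prefix sums.  The cost surface is scanned
    feature-major so equal-gain ties resolve to the lowest feature index and
    then the lowest threshold.
    """
    m = len(y)
    if m < 2 * min_leaf:
        return None
    Xs = X[:, feat_idx]
    order = np.argsort(Xs, axis=0, kind="stable")
    xs = np.take_along_axis(Xs, order, axis=0)
    ys = y[order]

    sizes_l = np.arange(1, m)[:, None].astype(float)          # (m-1, 1)
    sizes_r = m - sizes_l
    if task == "gini":
        c1 = np.cumsum(ys, axis=0)[:-1]                        # class-1 in left
        p_l = c1 / sizes_l
        p_r = (y.sum() - c1) / sizes_r
        cost = sizes_l * p_l * (1 - p_l) + sizes_r * p_r * (1 - p_r)
    else:  # squared error
        s = np.cumsum(ys, axis=0)[:-1]
        sq = np.cumsum(ys * ys, axis=0)[:-1]
        tot_s, tot_sq = ys.sum(axis=0), (ys * ys).sum(axis=0)
        cost = (sq - s * s / sizes_l) + ((tot_sq - sq) - (tot_s - s) ** 2 / sizes_r)

    invalid = xs[1:] <= xs[:-1]                                # no distinct boundary
    if min_leaf > 1:
        pos = np.arange(1, m)
        invalid |= ((pos < min_leaf) | (m - pos < min_leaf))[:, None]
    cost = np.where(invalid, np.inf, cost)

    # parent cost, for the gain
    if task == "gini":
        p = y.mean()
        parent = m * p * (1 - p)
    else:
        parent = (y * y).sum() - m * y.mean() ** 2

    flat = cost.T.reshape(-1)                                  # feature-major scan
    best = int(np.argmin(flat))
    best_cost = flat[best]
    if not np.isfinite(best_cost):
        return None
    # a zero-gain split is still taken (as in standard CART): children are
    # strictly smaller, and descendants may split usefully (e.g. XOR)
    gain = parent - best_cost
    f_local, pos = divmod(best, m - 1)
    thr = 0.5 * (xs[pos, f_local] + xs[pos + 1, f_local])
    return int(feat_idx[f_local]), float(thr), float(gain)


@dataclass
class _Builder:
    feature: list = dc_field(default_factory=list)
    threshold: list = dc_field(default_factory=list)
    left: list = dc_field(default_factory=list)
    right: list = dc_field(default_factory=list)
    value: list = dc_field(default_factory=list)
    cover: list = dc_field(default_factory=list)
    leaf_rows: dict = dc_field(default_factory=dict)

    def add(self) -> int:
        for lst, fill in ((self.feature, LEAF), (self.threshold, np.nan), (self.left, LEAF),
                          (self.right, LEAF), (self.value, 0.0), (self.cover, 0.0)):
            lst.append(fill)
        return len(self.feature) - 1

    def to_tree(self) -> Tree:
        return Tree(
            np.array(self.feature, dtype=np.int64), np.array(self.threshold, dtype=float),
            np.array(self.left, dtype=np.int64), np.array(self.right, dtype=np.int64),
            np.array(self.value, dtype=float), np.array(self.cover, dtype=float),
        )


def _grow(X: np.ndarray, y: np.ndarray, *, task: str, max_depth: int,
          min_samples_split: int, min_samples_leaf: int,
          max_features: int | None, rng: np.random.Generator | None) -> _Builder:
    n_feat = X.shape[1]
    b = _Builder()
    root = b.add()
    stack = [(root, np.arange(len(y)), 0)]
    while stack:
        node, rows, depth = stack.pop()
        yn = y[rows]
        b.cover[node] = float(len(rows))
        leaf_value = yn.mean() if len(rows) else 0.0
        split = None
        pure = np.all(yn == yn[0]) if task == "gini" else False
        if depth < max_depth and len(rows) >= min_samples_split and not pure:
            if max_features is not None and max_features < n_feat:
                feat_idx = np.sort(rng.choice(n_feat, size=max_features, replace=False))
            else:
                feat_idx = np.arange(n_feat)
            split = _best_split(X[rows], yn, feat_idx, min_samples_leaf, task)
        if split is None:
            b.value[node] = float(leaf_value)
            b.leaf_rows[node] = rows
            continue
        f, thr, _ = split
        go_left = X[rows, f] <= thr
        lchild, rchild = b.add(), b.add()
        b.feature[node], b.threshold[node] = f, thr
        b.left[node], b.right[node] = lchild, rchild
        stack.append((rchild, rows[~go_left], depth + 1))
        stack.append((lchild, rows[go_left], depth + 1))
    return b


def fit_cart(X: np.ndarray, y: np.ndarray, *, max_depth: int = 90,
             min_samples_split: int = 5, min_samples_leaf: int = 2,
             criterion: str = "gini") -> Tree:
    """Greedy CART classification tree; leaves hold class-1 probabilities.

    An all-one-class input yields a single leaf predicting that class.
    Deterministic given data and parameters.
    """
    if criterion != "gini":
        raise ValueError("only the gini criterion is supported for classification")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    b = _grow(X, y, task="gini", max_depth=max_depth, min_samples_split=min_samples_split,
              min_samples_leaf=min_samples_leaf, max_features=None, rng=None)
    return b.to_tree()


def fit_forest(X: np.ndarray, y: np.ndarray, *, n_trees: int = 100,
               max_depth: int = 90, min_samples_split: int = 5,
               min_samples_leaf: int = 2, max_features: int | str | None = "sqrt",
               bootstrap: bool = True, seed: int = 0) -> TreeEnsemble:
    """Bagged voting forest: bootstrap rows, random feature subset per split.

    Combine rule is the average of member-tree class probabilities.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if isinstance(max_features, str):
        if max_features != "sqrt":
            raise ValueError(f"unknown max_features spec {max_features!r}")
        max_features = max(1, int(np.sqrt(p)))
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        rows = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        b = _grow(X[rows], y[rows], task="gini", max_depth=max_depth,
                  min_samples_split=min_samples_split, min_samples_leaf=min_samples_leaf,
                  max_features=max_features, rng=rng)
        trees.append(b.to_tree())
    return TreeEnsemble(
        trees=trees, combine="average_probability", n_features=p,
        metadata={"n_trees": n_trees, "max_depth": max_depth,
                  "min_samples_split": min_samples_split,
                  "min_samples_leaf": min_samples_leaf, "seed": seed},
    )


def fit_gbm(X: np.ndarray, y: np.ndarray, *, n_rounds: int = 100,
            learning_rate: float = 0.1, max_depth: int = 3,
            min_samples_split: int = 5, min_samples_leaf: int = 2,
            colsample: float = 1.0, seed: int = 0) -> TreeEnsemble:
    """Gradient-boosted trees with logistic loss.

    Each round fits a squared-error regression tree to the negative gradient
    (``y - p``) of the logistic loss and sets leaf values with a single
    Newton step, as standard boosting libraries do.  Leaf values are stored
    pre-scaled by the learning rate, so the ensemble margin is
    ``base_margin + sum of tree outputs``.
    """
    if n_rounds < 1 or learning_rate <= 0:
        raise ValueError("need n_rounds >= 1 and learning_rate > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    p1 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    base = float(np.log(p1 / (1 - p1)))
    margin = np.full(n, base)
    max_features = None
    if colsample < 1.0:
        max_features = max(1, int(round(colsample * p)))
    trees = []
    for _ in range(n_rounds):
        prob = _sigmoid(margin)
        grad = y - prob                       # negative gradient of logloss
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite boosting gradient")
        hess = prob * (1 - prob)
        b = _grow(X, grad, task="sse", max_depth=max_depth,
                  min_samples_split=min_samples_split, min_samples_leaf=min_samples_leaf,
                  max_features=max_features, rng=rng)
        for leaf, rows in b.leaf_rows.items():
            step = grad[rows].sum() / max(hess[rows].sum(), _EPS)
            b.value[leaf] = learning_rate * step
        tree = b.to_tree()
        margin += tree.predict(X)
        trees.append(tree)
    return TreeEnsemble(
        trees=trees, combine="additive_margin", n_features=p, base_margin=base,
        learning_rate=learning_rate,
        metadata={"n_rounds": n_rounds, "max_depth": max_depth,
                  "min_samples_split": min_samples_split,
                  "min_samples_leaf": min_samples_leaf, "colsample": colsample,
                  "seed": seed},
    )


# ---------------------------------------------------------------------------
# Conversion of externally trained scikit-learn tree models


def _convert_sklearn_tree(t, value_fn) -> Tree:
    n = t.node_count
    feature = np.where(t.children_left == -1, LEAF, t.feature).astype(np.int64)
    threshold = np.where(t.children_left == -1, np.nan, t.threshold)
    left = t.children_left.astype(np.int64)
    right = t.children_right.astype(np.int64)
    value = np.array([value_fn(t, i) if left[i] == -1 else 0.0 for i in range(n)])
    return Tree(feature, threshold, left.clip(min=LEAF), right.clip(min=LEAF),
                value, t.weighted_n_node_samples.astype(float))


def from_sklearn(estimator) -> TreeEnsemble:
    """Export a fitted scikit-learn tree model to the JSON tree schema.

    Supports voting forests (``RandomForestClassifier``,
    ``ExtraTreesClassifier``: combine = average probability) and
    ``GradientBoostingClassifier`` (combine = additive margin, learning rate
    folded into leaf values).  The result is attributable by the tree-path
    Shapley algorithm exactly like an in-repo ensemble.
    """
    name = type(estimator).__name__
    if name in ("RandomForestClassifier", "ExtraTreesClassifier"):
        def prob(t, i):
            counts = t.value[i, 0]
            return float(counts[1] / counts.sum()) if counts.sum() else 0.5
        trees = [_convert_sklearn_tree(e.tree_, prob) for e in estimator.estimators_]
        return TreeEnsemble(trees=trees, combine="average_probability",
                            n_features=estimator.n_features_in_,
                            metadata={"source": name})
    if name == "GradientBoostingClassifier":
        lr = estimator.learning_rate
        def margin(t, i):
            return float(t.value[i, 0, 0]) * lr
        trees = [_convert_sklearn_tree(e.tree_, margin) for e in estimator.estimators_[:, 0]]
        # initial raw prediction = log-odds of the training base rate
        X0 = np.zeros((1, estimator.n_features_in_))
        base = float(estimator._raw_predict_init(X0)[0, 0])
        return TreeEnsemble(trees=trees, combine="additive_margin",
                            n_features=estimator.n_features_in_, base_margin=base,
                            learning_rate=lr, metadata={"source": name})
    raise TypeError(f"cannot convert {name} to a tree ensemble")
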
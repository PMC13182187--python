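"""Shapley-value feature attribution.

Four routes to the same game-theoretic quantity, each suited to a different
regime:

``exact_shapley``
    Classical weighted-coalition enumeration with an *interventional* value
    function: features inside a coalition are fixed to the explained
    instance, the rest are replaced by rows of an explicit background set
    and averaged.  Exponential in the number of played features, so capped
    (default 16); it is the oracle the other estimators are checked against.

``sampling_shapley``
    Unbiased permutation-sampling estimator of the same value, with
    Monte-Carlo standard errors; the practical route for model-agnostic
    attribution at connectome dimensionality (1378 features).

``tree_shapley``
    Polynomial-time path-dependent algorithm for binary-split tree
    ensembles.  Absent features are marginalized along tree paths using the
    per-node training *cover* counts, so no separate background set is
    needed; attributions are additive over trees and satisfy local accuracy
    exactly.  This is the route the cross-validated pipeline uses.

``interaction_value``
    The pairwise Shapley interaction index: the coalition-weighted average
    of the second-order difference
    ``f(S+{i,j}) - f(S+{i}) - f(S+{j}) + f(S)``, symmetric in ``(i, j)`` and
    zero for additive models.

Attributions of an ``additive_margin`` ensemble live in margin (log-odds)
units; those of an ``average_probability`` ensemble in probability units.
In both cases ``base_value + phi.sum()`` equals the model output at the
explained instance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .trees import Tree, TreeEnsemble


class EnumerationLimitError(ValueError):
    """Too many features for exact coalition enumeration."""


@dataclass
class AttributionVector:
    """Per-feature Shapley values for one explained instance."""

    phi: np.ndarray
    base_value: float
    x: np.ndarray
    stderr: np.ndarray | None = None

    @property
    def total(self) -> float:
        """Reconstructed model output: base value plus all attributions."""
        return float(self.base_value + self.phi.sum())


# ---------------------------------------------------------------------------
# interventional value function + exact enumeration


def _coalition_values(predict_fn, x, background, subset):
    """Value of every coalition S of `subset`, keyed by bitmask.

    Features outside `subset` stay fixed at the instance, so the grand
    coalition's value is exactly the model output at x.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0 or background.shape[1] != x.size:
        raise ValueError("background must be nonempty with the instance's dimensionality")
    m = len(subset)
    values = np.empty(2 ** m)
    data = background.copy()
    outside = np.setdiff1d(np.arange(x.size), subset)
    data[:, outside] = x[outside]
    for mask in range(2 ** m):
        rows = data.copy()
        for b in range(m):
            if mask >> b & 1:
                rows[:, subset[b]] = x[subset[b]]
        values[mask] = float(np.mean(predict_fn(rows)))
    return values


def exact_shapley(predict_fn, x, background, feature_subset=None, *,
                  enumeration_limit: int = 16) -> AttributionVector:
    """Shapley values by full coalition enumeration.

    ``feature_subset`` restricts the game to those features (the rest are
    held at the instance value and receive zero attribution); defaults to
    all features.  Satisfies efficiency, symmetry, dummy and linearity.
    """
    x = np.asarray(x, dtype=float).ravel()
    subset = np.arange(x.size) if feature_subset is None else np.asarray(feature_subset)
    m = len(subset)
    if m > enumeration_limit:
        raise EnumerationLimitError(
            f"{m} features exceed the enumeration limit ({enumeration_limit}); "
            "use sampling_shapley for high-dimensional instances"
        )
    values = _coalition_values(predict_fn, x, background, subset)
    fact = [math.factorial(i) for i in range(m + 1)]
    phi = np.zeros(x.size)
    for b, feat in enumerate(subset):
        acc = 0.0
        others = [bb for bb in range(m) if bb != b]
        for size in range(m):
            w = fact[size] * fact[m - size - 1] / fact[m]
            for combo in itertools.combinations(others, size):
                mask = sum(1 << bb for bb in combo)
                acc += w * (values[mask | (1 << b)] - values[mask])
        phi[feat] = acc
    return AttributionVector(phi=phi, base_value=float(values[0]), x=x)


def sampling_shapley(predict_fn, x, background, n_permutations: int = 200,
                     seed: int = 0, feature_subset=None,
                     permutations=None) -> AttributionVector:
    """Permutation-sampling Shapley estimator with standard errors.

    Each sampled feature order contributes one marginal-contribution sample
    per feature; the estimate is their mean and ``stderr`` the Monte-Carlo
    standard error.  Passing ``permutations`` explicitly (e.g. all ``M!``
    orders) makes the estimate exact.
    """
    x = np.asarray(x, dtype=float).ravel()
    subset = np.arange(x.size) if feature_subset is None else np.asarray(feature_subset)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if permutations is None:
        if n_permutations < 2:
            raise ValueError("need at least 2 permutations for a standard error")
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(len(subset)) for _ in range(n_permutations)]

    outside = np.setdiff1d(np.arange(x.size), subset)
    base_rows = background.copy()
    base_rows[:, outside] = x[outside]
    base_value = float(np.mean(predict_fn(base_rows)))

    samples = np.zeros((len(permutations), len(subset)))
    for p_i, perm in enumerate(permutations):
        rows = base_rows.copy()
        prev = base_value  # v(empty set) is the same for every order
        for pos in perm:
            pos = int(pos)
            feat = subset[pos]
            rows[:, feat] = x[feat]
            cur = float(np.mean(predict_fn(rows)))
            samples[p_i, pos] = cur - prev
            prev = cur
    phi = np.zeros(x.size)
    phi[subset] = samples.mean(axis=0)
    stderr = np.zeros(x.size)
    if len(permutations) > 1:
        stderr[subset] = samples.std(axis=0, ddof=1) / math.sqrt(len(permutations))
    return AttributionVector(phi=phi, base_value=base_value, x=x, stderr=stderr)


# ---------------------------------------------------------------------------
# path-dependent tree algorithm


def _tree_expectation(tree: Tree) -> float:
    """Cover-weighted expected leaf value of one tree."""
    total = 0.0
    stack = [(0, 1.0)]
    while stack:
        node, w = stack.pop()
        if tree.is_leaf(node):
            total += w * tree.value[node]
        else:
            c = tree.cover[node]
            stack.append((int(tree.left[node]), w * tree.cover[tree.left[node]] / c))
            stack.append((int(tree.right[node]), w * tree.cover[tree.right[node]] / c))
    return total


def _tree_shap_batch(tree: Tree, X: np.ndarray, phi: np.ndarray) -> None:
    """Accumulate path-dependent Shapley values of one tree for all rows.

    The recursion walks every tree node once; the bookkeeping over the
    feature path (extend/unwind of coalition-size weights) is vectorized
    across the explained rows, which share the path's feature sequence and
    cover ratios and differ only in which child is on their decision path.
    ``phi`` has shape (n_rows, n_features) and is modified in place.
    """
    n = len(X)
    ones, zeros = np.ones(n), np.zeros(n)

    def extend(m, pz, po, pi):
        # m: list of [d, z(n,), o(n,), w(n,)]
        l = len(m)
        m = [[e[0], e[1], e[2], e[3].copy()] for e in m]
        m.append([pi, pz, po, ones.copy() if l == 0 else zeros.copy()])
        for i in range(l - 1, -1, -1):
            m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
            m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
        return m

    def unwind(m, k):
        l = len(m) - 1
        z_k, o_k = m[k][1], m[k][2]
        hot = o_k != 0
        o_safe = np.where(hot, o_k, 1.0)
        z_safe = np.where(z_k != 0, z_k, 1.0)
        acc = m[l][3].copy()
        new_w = [None] * l
        for j in range(l - 1, -1, -1):
            t = m[j][3]
            w_hot = acc * (l + 1) / ((j + 1) * o_safe)
            w_cold = t * (l + 1) / (z_safe * (l - j))
            new_w[j] = np.where(hot, w_hot, w_cold)
            acc = np.where(hot, t - w_hot * z_k * (l - j) / (l + 1), acc)
        out = []
        for j in range(l):
            src = m[j] if j < k else m[j + 1]  # drop element k, keep weights in place
            out.append([src[0], src[1], src[2], new_w[j]])
        return out

    def unwound_sum(m, k):
        l = len(m) - 1
        z_k, o_k = m[k][1], m[k][2]
        hot = o_k != 0
        o_safe = np.where(hot, o_k, 1.0)
        z_safe = np.where(z_k != 0, z_k, 1.0)
        total = zeros.copy()
        acc = m[l][3].copy()
        for j in range(l - 1, -1, -1):
            w_hot = acc * (l + 1) / ((j + 1) * o_safe)
            w_cold = m[j][3] * (l + 1) / (z_safe * (l - j))
            total += np.where(hot, w_hot, w_cold)
            acc = np.where(hot, m[j][3] - w_hot * z_k * (l - j) / (l + 1), acc)
        return total

    def recurse(node, m, pz, po, pi):
        m = extend(m, pz, po, pi)
        if tree.is_leaf(node):
            v = tree.value[node]
            for i in range(1, len(m)):
                w = unwound_sum(m, i)
                phi[:, m[i][0]] += w * (m[i][2] - m[i][1]) * v
            return
        d = int(tree.feature[node])
        go_left = X[:, d] <= tree.threshold[node]
        iz, io = ones, ones
        k = next((i for i in range(1, len(m)) if m[i][0] == d), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = unwind(m, k)
        cov = tree.cover[node]
        lchild, rchild = int(tree.left[node]), int(tree.right[node])
        recurse(lchild, m, iz * tree.cover[lchild] / cov, np.where(go_left, io, 0.0), d)
        recurse(rchild, m, iz * tree.cover[rchild] / cov, np.where(go_left, 0.0, io), d)

    recurse(0, [], ones, ones, -1)


def tree_shapley(ensemble: TreeEnsemble, X: np.ndarray) -> list[AttributionVector]:
    """Path-dependent Shapley attribution of a tree ensemble.

    ``X`` may be a single instance or a batch; one attribution per row is
    returned.  Attributions are additive over trees (scaled by 1/n_trees
    for a voting forest) and satisfy local accuracy exactly:
    ``base_value + phi.sum()`` equals the margin (boosting) or the averaged
    probability (forest) at the instance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ensemble.n_features:
        raise ValueError(f"expected {ensemble.n_features} features, got {X.shape[1]}")
    for t in ensemble.trees:
        if np.isnan(t.cover).any() or (t.cover <= 0).any():
            raise ValueError("tree covers are missing or non-positive; cannot attribute")
    phi = np.zeros_like(X)
    expect = 0.0
    for t in ensemble.trees:
        _tree_shap_batch(t, X, phi)
        expect += _tree_expectation(t)
    if ensemble.combine == "average_probability":
        phi /= len(ensemble.trees)
        base = expect / len(ensemble.trees)
    else:
        base = ensemble.base_margin + expect
    return [AttributionVector(phi=phi[i], base_value=float(base), x=X[i]) for i in range(len(X))]


# ---------------------------------------------------------------------------
# pairwise interaction index


def interaction_value(predict_fn, x, i: int, j: int, background, feature_subset=None, *,
                      enumeration_limit: int = 16) -> float:
    """Pairwise Shapley interaction of features ``i`` and ``j`` at ``x``.

    The coalition-weighted average, over all subsets S excluding i and j, of
    the second-order difference of the interventional value function; the
    weight of a subset of size s is ``s! (M - s - 2)! / (2 (M - 1)!)``.
    Symmetric in (i, j); identically zero for additive models.
    """
    if i == j:
        raise ValueError("interaction is defined only for distinct features (i != j)")
    x = np.asarray(x, dtype=float).ravel()
    subset = np.arange(x.size) if feature_subset is None else np.asarray(feature_subset)
    if i not in subset or j not in subset:
        raise ValueError("both features must belong to the played subset")
    m = len(subset)
    if m > enumeration_limit:
        raise EnumerationLimitError(
            f"{m} features exceed the enumeration limit ({enumeration_limit})"
        )
    values = _coalition_values(predict_fn, x, background, subset)
    pos = {int(f): b for b, f in enumerate(subset)}
    bi, bj = 1 << pos[int(i)], 1 << pos[int(j)]
    others = [b for b in range(m) if (1 << b) not in (bi, bj)]
    fact = [math.factorial(s) for s in range(m + 1)]
    total = 0.0
    for size in range(len(others) + 1):
        w = fact[size] * fact[m - size - 2] / (2 * fact[m - 1])
        for combo in itertools.combinations(others, size):
            mask = sum(1 << b for b in combo)
            delta = (values[mask | bi | bj] - values[mask | bi]
                     - values[mask | bj] + values[mask])
            total += w * delta
    return float(total)
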
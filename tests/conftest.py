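"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import numpy as np
import pytest

from fncxplain.trees import Tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pearson_by_hand(x1, x2):
    """Direct evaluation of the correlation formula from expanded sums."""
    x1 = list(map(float, x1))
    x2 = list(map(float, x2))
    n = len(x1)
    m1 = sum(x1) / n
    m2 = sum(x2) / n
    num = sum((a - m1) * (b - m2) for a, b in zip(x1, x2))
    den = math.sqrt(sum((a - m1) ** 2 for a in x1)) * math.sqrt(sum((b - m2) ** 2 for b in x2))
    return num / den


def tree_expvalue(tree: Tree, x, S):
    """Path-dependent value function: features outside S are marginalized
    down the tree with cover weights; features in S follow the instance."""
    def rec(n):
        if tree.is_leaf(n):
            return tree.value[n]
        d = int(tree.feature[n])
        l, r = int(tree.left[n]), int(tree.right[n])
        if d in S:
            return rec(l) if x[d] <= tree.threshold[n] else rec(r)
        c = tree.cover[n]
        return (tree.cover[l] * rec(l) + tree.cover[r] * rec(r)) / c
    return rec(0)


def brute_force_tree_shapley(tree: Tree, x, n_features):
    """Shapley values of the path-dependent game by full coalition enumeration."""
    phi = np.zeros(n_features)
    for i in range(n_features):
        others = [f for f in range(n_features) if f != i]
        for s in range(len(others) + 1):
            w = math.factorial(s) * math.factorial(n_features - s - 1) / math.factorial(n_features)
            for combo in itertools.combinations(others, s):
                S = set(combo)
                phi[i] += w * (tree_expvalue(tree, x, S | {i}) - tree_expvalue(tree, x, S))
    return phi


def random_tree(rng, n_features=3, depth=3):
    """A random binary tree with consistent covers, possibly repeating
    features along a path (the hard case for path bookkeeping)."""
    feature, threshold, left, right, value, cover = [], [], [], [], [], []

    def build(d, cov):
        idx = len(feature)
        feature.append(-1); threshold.append(np.nan)
        left.append(-1); right.append(-1); value.append(0.0); cover.append(cov)
        if d == 0 or cov < 2 or rng.random() < 0.3:
            value[idx] = float(rng.normal())
            return idx
        feature[idx] = int(rng.integers(n_features))
        threshold[idx] = float(rng.normal())
        cl = int(rng.integers(1, cov))
        left[idx] = build(d - 1, cl)
        right[idx] = build(d - 1, cov - cl)
        return idx

    build(depth, int(rng.integers(8, 40)))
    return Tree(np.array(feature), np.array(threshold, dtype=float),
                np.array(left), np.array(right),
                np.array(value, dtype=float), np.array(cover, dtype=float))
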
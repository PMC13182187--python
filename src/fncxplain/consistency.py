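"""Cross-model consistency of attributed features.

Per-feature importance is the mean absolute Shapley value over every
attributed held-out row, pooled across folds and repetitions (the ordering
used by standard SHAP summary plots).  The top-k sets of different model
architectures are then compared by exact set arithmetic — pairwise and
all-model intersection counts, and the per-model percentage of features
shared with at least one other model — and mapped onto network domains via
the component atlas.  On synthetic cohorts, recovery of the planted
features is scored as recall@k / precision@k.

The direction attached to each top feature is the sign of the Spearman rank
correlation between the feature's value and its Shapley value across
samples: +1 means higher connectivity pushes the model toward class 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fnc import ComponentAtlas, domain_pair, pair_of_index
from .simulate import PlantedTruth


@dataclass(frozen=True)
class ImportanceRanking:
    """Features sorted by mean |phi|, ties broken by feature index."""

    order: np.ndarray    # feature indices, most important first
    scores: np.ndarray   # mean |phi| per feature (unsorted, indexed by feature)

    @property
    def n_features(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class TopKSet:
    """The k most important features of one model, with direction signs."""

    features: tuple[int, ...]          # in rank order
    directions: dict[int, int]         # feature -> {-1, 0, +1}
    scores: dict[int, float]

    @property
    def as_set(self) -> frozenset:
        return frozenset(self.features)

    @property
    def k(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class OverlapSummary:
    pairwise: dict[tuple[str, str], int]
    all_models: int
    pct_with_any: dict[str, float]     # % of a model's top-k shared with >= 1 other
    k: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "pairwise": {f"{a}&{b}": c for (a, b), c in self.pairwise.items()},
            "all_models": self.all_models,
            "pct_with_any": self.pct_with_any,
        }


def rank_features(phi: np.ndarray) -> ImportanceRanking:
    """Mean-|phi| ranking over pooled attribution rows (rows x features)."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if phi.size == 0:
        raise ValueError("no attribution rows to rank")
    scores = np.abs(phi).mean(axis=0)
    # stable sort on -score keeps lower feature indices first among ties
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(order=order, scores=scores)


def direction_sign(feature_values: np.ndarray, phi_values: np.ndarray) -> int:
    """Sign of the rank correlation between a feature's value and its phi."""
    if len(feature_values) < 2 or np.ptp(feature_values) == 0 or np.ptp(phi_values) == 0:
        return 0
    rho = sps.spearmanr(feature_values, phi_values).statistic
    if np.isnan(rho) or rho == 0:
        return 0
    return int(np.sign(rho))


def top_k(ranking: ImportanceRanking, X: np.ndarray, phi: np.ndarray, k: int = 20) -> TopKSet:
    """First k features of a ranking, with per-feature direction signs."""
    if k > ranking.n_features:
        raise ValueError(f"k={k} exceeds the {ranking.n_features} available features")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    feats = tuple(int(f) for f in ranking.order[:k])
    directions = {f: direction_sign(X[:, f], phi[:, f]) for f in feats}
    scores = {f: float(ranking.scores[f]) for f in feats}
    return TopKSet(features=feats, directions=directions, scores=scores)


def overlap(topk_sets: dict[str, TopKSet]) -> OverlapSummary:
    """Exact intersection statistics across the models' top-k sets."""
    if len(topk_sets) < 2:
        raise ValueError("need at least two models to compute overlap")
    ks = {name: s.k for name, s in topk_sets.items()}
    if len(set(ks.values())) != 1:
        raise ValueError(f"top-k sets have unequal k: {ks}")
    k = next(iter(ks.values()))
    names = list(topk_sets)
    sets = {n: topk_sets[n].as_set for n in names}
    pairwise = {(a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)}
    common = frozenset.intersection(*sets.values())
    pct = {}
    for n in names:
        others = frozenset.union(*(sets[m] for m in names if m != n))
        pct[n] = 100.0 * len(sets[n] & others) / k
    return OverlapSummary(pairwise=pairwise, all_models=len(common), pct_with_any=pct, k=k)


@dataclass(frozen=True)
class DomainContribution:
    per_domain: dict[str, int]                  # features incident to each domain
    per_domain_pair: dict[tuple[str, str], int]

    def to_dict(self) -> dict:
        return {
            "per_domain": dict(self.per_domain),
            "per_domain_pair": {f"{a}-{b}": c for (a, b), c in self.per_domain_pair.items()},
        }


def domain_contribution(topk: TopKSet, atlas: ComponentAtlas) -> DomainContribution:
    """Count top-k features per network domain and per domain pair.

    A between-domain feature increments both endpoint domains; a
    within-domain feature increments its domain once.  Domain-pair counts
    always sum to k.
    """
    per_domain: dict[str, int] = {}
    per_pair: dict[tuple[str, str], int] = {}
    for f in topk.features:
        di, dj = domain_pair(f, atlas)
        per_pair[(di, dj)] = per_pair.get((di, dj), 0) + 1
        per_domain[di] = per_domain.get(di, 0) + 1
        if dj != di:
            per_domain[dj] = per_domain.get(dj, 0) + 1
    return DomainContribution(per_domain=per_domain, per_domain_pair=per_pair)


def recovery(topk: TopKSet, truth: PlantedTruth) -> tuple[float, float]:
    """Planted-feature recovery: (recall@k, precision@k)."""
    planted = truth.indices
    if not planted:
        raise ValueError("planted truth is empty")
    hit = len(set(topk.features) & planted)
    return hit / len(planted), hit / topk.k


def ranking_table(topk: TopKSet, atlas: ComponentAtlas | None = None) -> pd.DataFrame:
    """Flat table of a top-k set: rank, component pair, domains, direction."""
    rows = []
    n_comp = len(atlas) if atlas is not None else None
    for rank, f in enumerate(topk.features, start=1):
        row = {"rank": rank, "feature_id": f, "mean_abs_phi": topk.scores[f],
               "direction": topk.directions[f]}
        if atlas is not None:
            i, j = pair_of_index(f, n_comp)
            row.update(comp_i=i + 1, comp_j=j + 1,
                       domain_i=atlas.domain_of(i), domain_j=atlas.domain_of(j))
        rows.append(row)
    return pd.DataFrame(rows)


def edge_list(topk: TopKSet, atlas: ComponentAtlas) -> pd.DataFrame:
    """Connectogram export: one edge per top-k feature.

    ``higher_in`` names the class with the higher connectivity at that edge
    (class 1 when the direction sign is positive, i.e. increased
    connectivity pushes the model toward class 1).
    """
    rows = []
    for f in topk.features:
        i, j = pair_of_index(f, len(atlas))
        d = topk.directions[f]
        rows.append({
            "feature_id": f, "comp_i": i + 1, "comp_j": j + 1,
            "domain_i": atlas.domain_of(i), "domain_j": atlas.domain_of(j),
            "higher_in": {1: "class1", -1: "class2", 0: "tied"}[d],
        })
    return pd.DataFrame(rows)


def beeswarm_table(topk: TopKSet, subject_ids, X: np.ndarray, phi: np.ndarray) -> pd.DataFrame:
    """Long-format (feature, sample, value, phi) data for summary plots."""
    X = np.atleast_2d(X)
    phi = np.atleast_2d(phi)
    frames = []
    for f in topk.features:
        frames.append(pd.DataFrame({
            "feature_id": f, "subject_id": list(subject_ids),
            "feature_value": X[:, f], "phi": phi[:, f],
        }))
    return pd.concat(frames, ignore_index=True)
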
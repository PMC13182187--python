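"""Functional network connectivity (FNC) construction and indexing.

A subject's FNC matrix is the Pearson correlation between every pair of
component time courses.  With ``n`` components the strictly-upper-triangular
part, read in row-major order with ``i < j`` and 0-based component indices,
is the subject's feature vector of length ``n(n-1)/2`` — 1378 features for
the default 53-component atlas.  That ordering is the canonical one used
everywhere in this package, so feature ranks are comparable across runs and
models.  Correlations are used raw (no Fisher z-transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

DOMAINS = ("SCN", "ADN", "SMN", "VSN", "CCN", "DMN", "CBN")


class DegenerateTimeCourseError(ValueError):
    """Raised when a component time course has zero variance."""


@dataclass
class TimeCourseSet:
    """Component time courses for one subject (components x timepoints)."""

    subject_id: str
    values: np.ndarray
    component_ids: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time courses must be a 2-D components x timepoints array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints per component")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in time courses of {self.subject_id!r}")
        if self.component_ids is None:
            self.component_ids = list(range(1, self.values.shape[0] + 1))
        elif len(self.component_ids) != self.values.shape[0]:
            raise ValueError("component_ids length does not match row count")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Component:
    id: int
    label: str
    domain: str
    peak_mm: tuple[float, float, float] | None = None


@dataclass
class ComponentAtlas:
    """Ordered list of components with their domain assignment.

    Domains must partition the components.  The default atlas
    (:func:`default_atlas`) has 53 components in 7 domains.
    """

    components: list[Component] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate component ids in atlas")
        bad = [c.id for c in self.components if c.domain not in DOMAINS]
        if bad:
            raise ValueError(f"components {bad} have domains outside {DOMAINS}")

    def __len__(self) -> int:
        return len(self.components)

    def domain_of(self, index: int) -> str:
        """Domain of the component at 0-based position ``index``."""
        if not 0 <= index < len(self.components):
            raise KeyError(f"component index {index} not covered by atlas (n={len(self)})")
        return self.components[index].domain

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for c in self.components:
            if c.domain not in seen:
                seen.append(c.domain)
        return seen

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComponentAtlas":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comps = [
            Component(
                id=int(c["id"]),
                label=str(c["label"]),
                domain=str(c["domain"]),
                peak_mm=tuple(c["peak_mm"]) if c.get("peak_mm") else None,
            )
            for c in raw["components"]
        ]
        return cls(comps)


def default_atlas() -> ComponentAtlas:
    """The bundled 53-component / 7-domain atlas."""
    ref = resources.files("fncxplain.data").joinpath("neuromark53.yaml")
    with resources.as_file(ref) as path:
        return ComponentAtlas.from_yaml(path)


def compute_fnc(tc: TimeCourseSet) -> np.ndarray:
    """Pearson-correlation FNC matrix of one subject's time courses.

    Returns a symmetric ``n x n`` matrix with unit diagonal and entries in
    ``[-1, 1]``.  A zero-variance component is a hard error: a silent NaN
    would propagate into every downstream ranking.
    """
    x = tc.values
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [tc.component_ids[i] for i in dead]
        raise DegenerateTimeCourseError(
            f"zero-variance time course(s) for component(s) {names} of subject {tc.subject_id!r}"
        )
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def n_pairs(n_components: int) -> int:
    return n_components * (n_components - 1) // 2


def vectorize(m: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Strictly-upper-triangular entries of a symmetric matrix, row-major."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("FNC matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("FNC matrix must be symmetric")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(v: np.ndarray, n_components: int, *, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize`; the diagonal is filled with ``diagonal``."""
    v = np.asarray(v, dtype=float)
    expected = n_pairs(n_components)
    if v.shape != (expected,):
        raise ValueError(f"expected vector of length {expected} for n={n_components}, got {v.shape}")
    m = np.full((n_components, n_components), diagonal, dtype=float)
    iu = np.triu_indices(n_components, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


def pair_of_index(k: int, n_components: int) -> tuple[int, int]:
    """Component pair ``(i, j)``, ``i < j``, of feature index ``k``.

    Row-major over the strict upper triangle: feature 0 is (0, 1), feature
    ``n-2`` is (0, n-1), feature ``n-1`` is (1, 2), and so on.
    """
    total = n_pairs(n_components)
    if not 0 <= k < total:
        raise IndexError(f"feature index {k} out of range for n={n_components} ({total} pairs)")
    # Solve for the row: k sits after sum_{r<i} (n-1-r) features.
    # Closed form avoids a Python loop over 53 rows per call.
    i = int(n_components - 2 - math.floor(
        (math.sqrt(4 * n_components * (n_components - 1) - 8 * k - 7) - 1) / 2
    ))
    offset = k - (i * (2 * n_components - i - 1)) // 2
    return i, i + 1 + offset


def index_of_pair(i: int, j: int, n_components: int) -> int:
    """Feature index of component pair ``(i, j)``; order-insensitive."""
    if i == j:
        raise ValueError("diagonal entries are not features")
    if i > j:
        i, j = j, i
    if not (0 <= i < j < n_components):
        raise IndexError(f"pair ({i}, {j}) out of range for n={n_components}")
    return (i * (2 * n_components - i - 1)) // 2 + (j - i - 1)


def domain_pair(k: int, atlas: ComponentAtlas) -> tuple[str, str]:
    """Unordered domain pair of feature ``k`` under ``atlas``.

    The pair is returned in atlas domain order (so it is canonical);
    a within-domain feature returns the domain twice.
    """
    i, j = pair_of_index(k, len(atlas))
    di, dj = atlas.domain_of(i), atlas.domain_of(j)
    order = {d: r for r, d in enumerate(DOMAINS)}
    if order[dj] < order[di]:
        di, dj = dj, di
    return di, dj


def feature_names(n_components: int) -> list[str]:
    """Canonical column names ``f0000 .. fNNNN`` for the feature vector."""
    width = max(4, len(str(n_pairs(n_components) - 1)))
    return [f"f{k:0{width}d}" for k in range(n_pairs(n_components))]
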
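"""Synthetic cohorts with planted between-class connectivity differences.

The default configuration mirrors a schizophrenia-vs-control FNC study at
desk scale: 151 class-1 and 160 class-2 subjects, 1378 features (the
upper-triangle of a 53-component correlation matrix), an i.i.d. standard
normal baseline, and two contiguous blocks of 20 features each shifted by
``+effect_delta`` in class 1 and ``-effect_delta`` in class 2.  Ground truth
(which features were planted, and in which direction) is returned as a
separate object and written to a separate file so a classifier can never see
it.

A second generator plants effects at the *time-course* level instead: a
shared latent factor added to both members of a component pair in one class
only, which raises that pair's correlation and lets the full
time-course -> FNC -> classification path be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fnc import TimeCourseSet, index_of_pair, feature_names, n_pairs
from .table import LabeledFeatureTable

SITES = [f"site{i}" for i in range(1, 8)]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a planted-feature synthetic cohort.

    ``planted_blocks`` are half-open index ranges ``[start, stop)``; each
    block carries a direction from ``block_directions`` (+1: elevated in
    class 1, depressed in class 2; -1: the reverse).  ``effect_delta`` is the
    per-class mean shift, in baseline standard-deviation units, so the
    between-class mean gap at a planted feature is ``2 * effect_delta``.
    """

    n_class1: int = 151
    n_class2: int = 160
    n_features: int = 1378
    planted_blocks: tuple[tuple[int, int], ...] = ((100, 120), (700, 720))
    block_directions: tuple[int, ...] | None = None
    effect_delta: float = 0.8
    baseline: str = "normal"
    baseline_params: tuple[float, ...] = (0.0, 1.0)
    with_covariates: bool = True
    seed: int = 0

    def directions(self) -> tuple[int, ...]:
        if self.block_directions is None:
            return tuple(1 for _ in self.planted_blocks)
        return self.block_directions

    def validate(self) -> None:
        if self.n_class1 < 1 or self.n_class2 < 1:
            raise ConfigError("both classes need at least one sample")
        if self.effect_delta < 0:
            raise ConfigError("effect_delta must be >= 0")
        if self.baseline not in ("normal", "uniform"):
            raise ConfigError(f"unknown baseline family {self.baseline!r}")
        covered: set[int] = set()
        for start, stop in self.planted_blocks:
            if not (0 <= start < stop <= self.n_features):
                raise ConfigError(f"block ({start}, {stop}) outside [0, {self.n_features})")
            block = set(range(start, stop))
            if covered & block:
                raise ConfigError(f"block ({start}, {stop}) overlaps an earlier block")
            covered |= block
        dirs = self.directions()
        if len(dirs) != len(self.planted_blocks):
            raise ConfigError("block_directions length must match planted_blocks")
        if any(d not in (-1, 1) for d in dirs):
            raise ConfigError("block directions must be +1 or -1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic cohort: which features carry signal."""

    planted_indices: tuple[int, ...]
    direction: dict[int, int]
    config: SyntheticConfig | None = None

    @property
    def indices(self) -> set[int]:
        return set(self.planted_indices)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_indices": list(self.planted_indices),
            "direction": {str(k): v for k, v in self.direction.items()},
            "config": asdict(self.config) if self.config is not None else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        cfg = None
        if payload.get("config"):
            raw = payload["config"]
            for key in ("planted_blocks", "block_directions", "baseline_params"):
                if raw.get(key) is not None:
                    raw[key] = tuple(tuple(b) if isinstance(b, list) else b for b in raw[key])
            cfg = SyntheticConfig(**raw)
        return cls(
            planted_indices=tuple(payload["planted_indices"]),
            direction={int(k): v for k, v in payload["direction"].items()},
            config=cfg,
        )


def _baseline_draw(rng: np.random.Generator, cfg: SyntheticConfig, size) -> np.ndarray:
    if cfg.baseline == "normal":
        loc, scale = cfg.baseline_params
        return rng.normal(loc, scale, size=size)
    lo, hi = cfg.baseline_params
    return rng.uniform(lo, hi, size=size)


def _covariate_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Demographics resembling a multi-site clinical rs-fMRI cohort."""
    age = np.clip(rng.normal(37.0, 11.0, size=n), 18.0, 65.0).round(1)
    sex = rng.choice(["M", "F"], size=n, p=[0.75, 0.25])
    site = rng.choice(SITES, size=n)
    return pd.DataFrame({"age": age, "sex": sex, "site": site})


def generate_features(cfg: SyntheticConfig = SyntheticConfig()) -> tuple[LabeledFeatureTable, PlantedTruth]:
    """Draw a labeled feature table with planted class differences.

    Baseline features are i.i.d. from ``cfg.baseline``; each feature inside a
    planted block is shifted by ``direction * effect_delta`` in class 1 and
    ``-direction * effect_delta`` in class 2.  Identical config (including
    seed) gives a bit-identical table.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_class1 + cfg.n_class2
    X = _baseline_draw(rng, cfg, (n, cfg.n_features))
    labels = np.array(["class1"] * cfg.n_class1 + ["class2"] * cfg.n_class2)

    direction: dict[int, int] = {}
    for (start, stop), sign in zip(cfg.planted_blocks, cfg.directions()):
        for k in range(start, stop):
            direction[k] = sign
        shift = sign * cfg.effect_delta
        X[: cfg.n_class1, start:stop] += shift
        X[cfg.n_class1:, start:stop] -= shift

    cols = feature_names(_components_for(cfg.n_features))
    if len(cols) != cfg.n_features:  # non-triangular feature count: plain names
        width = max(4, len(str(cfg.n_features - 1)))
        cols = [f"f{k:0{width}d}" for k in range(cfg.n_features)]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "label", labels)
    frame.insert(0, "subject_id", [f"sub{i:04d}" for i in range(n)])
    covariate_cols: list[str] = []
    if cfg.with_covariates:
        cov = _covariate_frame(rng, n)
        for c in reversed(cov.columns):
            frame.insert(2, c, cov[c])
        covariate_cols = list(cov.columns)

    truth = PlantedTruth(tuple(sorted(direction)), direction, cfg)
    return LabeledFeatureTable(frame, covariate_cols), truth


def _components_for(n_features: int) -> int:
    """Component count whose pair count is n_features, else 0."""
    n = int((1 + np.sqrt(1 + 8 * n_features)) / 2)
    return n if n_pairs(n) == n_features else 0


@dataclass(frozen=True)
class LatentPairSpec:
    """Shared-factor loadings planted on component pairs, per class.

    For each ``(i, j, lam1, lam2)`` entry a unit-variance latent factor is
    added with loading ``lam1`` to components ``i`` and ``j`` of class-1
    subjects and ``lam2`` for class-2 subjects.  The induced correlation at
    the pair is ``lam^2 / (1 + lam^2) < 1`` by construction.
    """

    pairs: tuple[tuple[int, int, float, float], ...]
    n_components: int = 53
    n_timepoints: int = 157

    def validate(self) -> None:
        for i, j, _, _ in self.pairs:
            if i == j or not (0 <= i < self.n_components and 0 <= j < self.n_components):
                raise ConfigError(f"invalid component pair ({i}, {j})")
        if self.n_timepoints < 2:
            raise ConfigError("need at least 2 timepoints")


def generate_timecourses(
    cfg: SyntheticConfig, latent: LatentPairSpec
) -> tuple[list[TimeCourseSet], np.ndarray, PlantedTruth]:
    """Simulate per-subject component time courses with planted coupling.

    Returns the time-course sets, a label array (``"class1"``/``"class2"``)
    and the truth mapped to feature-vector indices.
    """
    cfg.validate()
    latent.validate()
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.n_class1, cfg.n_class2
    subjects: list[TimeCourseSet] = []
    labels = np.array(["class1"] * n1 + ["class2"] * n2)
    for s in range(n1 + n2):
        x = rng.normal(size=(latent.n_components, latent.n_timepoints))
        is_class1 = s < n1
        for i, j, lam1, lam2 in latent.pairs:
            lam = lam1 if is_class1 else lam2
            if lam != 0.0:
                g = rng.normal(size=latent.n_timepoints)
                x[i] += lam * g
                x[j] += lam * g
        subjects.append(TimeCourseSet(subject_id=f"sub{s:04d}", values=x))

    direction: dict[int, int] = {}
    for i, j, lam1, lam2 in latent.pairs:
        k = index_of_pair(i, j, latent.n_components)
        if lam1 != lam2:
            direction[k] = 1 if abs(lam1) > abs(lam2) else -1
    truth = PlantedTruth(tuple(sorted(direction)), direction, cfg)
    return subjects, labels, truth
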
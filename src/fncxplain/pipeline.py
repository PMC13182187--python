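"""End-to-end orchestration: data -> CV -> attribution -> consistency report.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes it
and writes a flat bundle of text artifacts to the output directory:

* ``metrics.tsv``       — per-iteration, per-fold, per-model metrics
* ``summary.tsv``       — mean +/- SD per model (pooled and per-iteration)
* ``ranking_<m>.tsv``   — full importance ranking per model
* ``topk_<m>.tsv``      — top-k table with component pairs and directions
* ``edges_<m>.tsv``     — connectogram edge list per model
* ``beeswarm_<m>.tsv``  — (feature, sample, value, phi) for the top-k
* ``overlap.json``      — cross-model intersection statistics
* ``domains.json``      — per-model network-domain contributions
* ``recovery.json``     — planted-feature recovery (simulated data only)
* ``truth.json``        — planted ground truth (simulated data only)
* ``manifest.json``     — config echo, seeds, package version, class counts

A failed stage leaves ``FAILED_<stage>`` in the output directory so partial
bundles are never mistaken for complete ones.  Reruns with the same config
reproduce every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consistency import (beeswarm_table, domain_contribution, edge_list, overlap,
                          rank_features, ranking_table, recovery, top_k)
from .cv_eval import run_repeated_cv
from .fnc import ComponentAtlas, default_atlas, n_pairs
from .io import read_feature_table, write_feature_table
from .models import build_model
from .simulate import PlantedTruth, SyntheticConfig, generate_features

#: Named analysis presets.  `fbirn-like` mirrors the multi-site clinical
#: protocol (age+sex+site confounds); `ukbb-like` regresses sex+site only,
#: because in an age-group contrast age *is* the label.
PRESETS = {
    "fbirn-like": {"confounds": ["age", "sex", "site"]},
    "ukbb-like": {"confounds": ["sex", "site"]},
}


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    source: str = "simulate"                   # simulate | feature-table
    feature_table: str | None = None           # path, when source=feature-table
    models: tuple[str, ...] = ("forest", "gbm", "ext")
    model_params: dict = field(default_factory=dict)
    preset: str = "fbirn-like"
    confounds: list[str] | None = None         # None: use preset's list
    k_folds: int = 10
    iterations: int = 1
    top_k: int = 20
    seed: int = 0
    out_dir: str = "fncxplain_out"
    synthetic: SyntheticConfig | None = None   # None: defaults with `seed`
    atlas_path: str | None = None

    def validate(self) -> None:
        if self.source not in ("simulate", "feature-table"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "feature-table" and not self.feature_table:
            raise ValueError("source 'feature-table' requires a feature_table path")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; have {sorted(PRESETS)}")
        if not self.models:
            raise ValueError("at least one model is required")
        if self.k_folds < 2 or self.iterations < 1 or self.top_k < 1:
            raise ValueError("need k_folds >= 2, iterations >= 1, top_k >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("planted_blocks", "block_directions", "baseline_params"):
                if syn.get(key) is not None:
                    syn[key] = tuple(tuple(b) if isinstance(b, list) else b for b in syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _model_factories(cfg: RunConfig) -> dict:
    factories = {}
    for name in cfg.models:
        params = dict(cfg.model_params.get(name, {}))
        factories[name] = (lambda n=name, p=params: build_model(n, **p))
    return factories


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run and write the artifact bundle.

    Returns a dict with the in-memory results (cv result, top-k sets,
    overlap summary, recovery scores) for programmatic use.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"

    def fail(exc: Exception):
        (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise exc

    try:
        stage = "data"
        truth: PlantedTruth | None = None
        if cfg.source == "simulate":
            syn = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
            table, truth = generate_features(syn)
            write_feature_table(table, out / "features.tsv")
            truth.to_json(out / "truth.json")
        else:
            table = read_feature_table(cfg.feature_table)

        confounds = cfg.confounds if cfg.confounds is not None else PRESETS[cfg.preset]["confounds"]
        confounds = [c for c in confounds if c in table.frame.columns]

        atlas: ComponentAtlas | None = None
        if cfg.atlas_path:
            atlas = ComponentAtlas.from_yaml(cfg.atlas_path)
        elif table.n_features == n_pairs(53):
            atlas = default_atlas()

        stage = "cross_validation"
        result = run_repeated_cv(
            table, _model_factories(cfg), k=cfg.k_folds, iterations=cfg.iterations,
            confound_cols=confounds, seed=cfg.seed, attribute=True,
        )
        result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
        summary = result.summary()
        summary.to_csv(out / "summary.tsv", sep="\t")
        result.summary(by_iteration=True).to_csv(out / "summary_by_iteration.tsv", sep="\t")

        stage = "consistency"
        topk_sets, domains, recov = {}, {}, {}
        for name, acc in result.attributions.items():
            X, phi = acc.stacked()
            ranking = rank_features(phi)
            tk = top_k(ranking, X, phi, k=cfg.top_k)
            topk_sets[name] = tk
            full = ranking_table(
                top_k(ranking, X, phi, k=ranking.n_features), atlas)
            full.to_csv(out / f"ranking_{name}.tsv", sep="\t", index=False)
            ranking_table(tk, atlas).to_csv(out / f"topk_{name}.tsv", sep="\t", index=False)
            beeswarm_table(tk, acc.subject_ids, X, phi).to_csv(
                out / f"beeswarm_{name}.tsv", sep="\t", index=False)
            if atlas is not None:
                edge_list(tk, atlas).to_csv(out / f"edges_{name}.tsv", sep="\t", index=False)
                domains[name] = domain_contribution(tk, atlas).to_dict()
            if truth is not None:
                rec, prec = recovery(tk, truth)
                recov[name] = {"recall_at_k": rec, "precision_at_k": prec, "k": cfg.top_k}

        ov = overlap(topk_sets) if len(topk_sets) >= 2 else None
        if ov is not None:
            (out / "overlap.json").write_text(json.dumps(ov.to_dict(), indent=2))
        if domains:
            (out / "domains.json").write_text(json.dumps(domains, indent=2))
        if recov:
            (out / "recovery.json").write_text(json.dumps(recov, indent=2))

        stage = "manifest"
        hashed = {k: v for k, v in cfg.to_jsonable().items() if k != "out_dir"}
        cfg_json = json.dumps(hashed, sort_keys=True, default=str)
        manifest = {
            "version": __version__,
            "config": cfg.to_jsonable(),
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "class_counts": {str(k): int(v) for k, v in table.class_counts().items()},
            "n_features": table.n_features,
            "confounds_used": confounds,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:  # noqa: BLE001 - marker file then re-raise
        fail(exc)

    return {"table": table, "cv": result, "topk": topk_sets, "overlap": ov,
            "recovery": recov, "domains": domains, "truth": truth, "manifest": manifest}
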
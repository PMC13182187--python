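"""Planted-feature recovery experiments: the package's validation harness.

These functions define, in one place, the synthetic validation protocol:
generate the default cohort (151 + 160 subjects, 1378 features, two planted
20-feature blocks shifted by +/-0.8 SD between classes), run the full
leakage-free repeated-CV pipeline with confound residualization, pool the
held-out Shapley attributions, and score how much of the planted truth the
top-k ranking recovers.  The null variant repeats this with no planted
effect, where recovery should sit at chance.
"""

from __future__ import annotations

import numpy as np

from .consistency import rank_features, recovery, top_k
from .cv_eval import run_repeated_cv
from .models import build_model
from .simulate import SyntheticConfig, generate_features

CONFOUNDS = ["age", "sex", "site"]


def recovery_run(model_name: str, seed: int, *, effect_delta: float = 0.8,
                 iterations: int = 5, k: int = 40, model_params: dict | None = None,
                 cv_k: int = 10) -> dict:
    """One recovery experiment: default cohort at ``seed``, one model.

    Returns recall@k / precision@k of the pooled mean-|phi| top-k against
    the planted truth, plus the CV accuracy and AUC.
    """
    cfg = SyntheticConfig(seed=seed, effect_delta=effect_delta)
    table, truth = generate_features(cfg)
    params = model_params or {}
    res = run_repeated_cv(
        table, {model_name: (lambda: build_model(model_name, **params))},
        k=cv_k, iterations=iterations, confound_cols=CONFOUNDS, seed=seed,
    )
    X, phi = res.attributions[model_name].stacked()
    tk = top_k(rank_features(phi), X, phi, k=k)
    rec, prec = recovery(tk, truth)
    return {
        "model": model_name, "seed": seed, "recall": rec, "precision": prec,
        "k": k, "n_planted": len(truth.indices),
        "accuracy": res.mean_metric(model_name),
        "auc": res.mean_metric(model_name, "auc"),
        "n_samples": len(table.frame),
    }


def recovery_suite(model_names=("forest", "gbm"), seeds=(0, 1, 2, 3, 4), **kw) -> list[dict]:
    """Recovery across models and seeds under the default study conditions."""
    return [recovery_run(m, s, **kw) for m in model_names for s in seeds]


def null_recall(seeds=range(20), *, k: int = 20, iterations: int = 1,
                model_name: str = "forest", model_params: dict | None = None) -> dict:
    """Chance-level control: no planted effect, so top-k is noise.

    Returns the mean recall@k over seeds together with the chance level and
    the 95% interval implied by drawing k features uniformly at random
    (hypergeometric over the 1378 features, 40 of them nominally 'planted').
    """
    seeds = list(seeds)
    recalls = []
    for seed in seeds:
        out = recovery_run(model_name, seed, effect_delta=0.0,
                           iterations=iterations, k=k, model_params=model_params)
        recalls.append(out["recall"])
    n_feat, n_planted = 1378, 40
    # hits per run ~ Hypergeometric(n_feat, n_planted, k)
    p = n_planted / n_feat
    mean_hits = k * p
    var_hits = k * p * (1 - p) * (n_feat - k) / (n_feat - 1)
    se_mean_recall = np.sqrt(var_hits / len(seeds)) / n_planted
    chance = mean_hits / n_planted
    return {
        "mean_recall": float(np.mean(recalls)), "recalls": recalls,
        "chance": chance,
        "interval95": (chance - 1.96 * se_mean_recall, chance + 1.96 * se_mean_recall),
        "k": k, "n_seeds": len(seeds),
    }
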
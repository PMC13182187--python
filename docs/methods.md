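# Methods

## The problem

Resting-state fMRI decompositions yield, per subject, a set of component
time courses (here 53 intrinsic connectivity networks grouped into seven
functional domains: subcortical SCN, auditory ADN, sensorimotor SMN, visual
VSN, cognitive-control CCN, default-mode DMN, cerebellar CBN).  Functional
network connectivity (FNC) is the Pearson correlation between every pair of
component time courses; the strictly-upper-triangular part of the 53 x 53
correlation matrix gives 1378 features per subject.  A classifier trained on
these features can separate clinical groups, but the scientific question is
*which* connections drive the separation.  This package answers it with
Shapley-value attribution computed inside a leakage-free cross-validation
protocol, and quantifies whether different classifier architectures agree on
the answer.

## Pipeline

1. **Features.**  `compute_fnc` computes per-subject Pearson FNC;
   `vectorize` maps the matrix to the canonical feature vector
   (strict upper triangle, row-major, 0-based, `i < j`).  Correlations are
   used raw — no Fisher z-transform — because monotone transforms do not
   change tree models' splits and raw `r` keeps features interpretable.
   A zero-variance time course raises an error rather than producing NaN:
   a silent NaN would propagate into every downstream ranking.
2. **Confounds.**  Age (continuous), sex and site (indicator-coded, first
   level dropped) are regressed out of every feature by per-feature OLS
   fitted on *training rows only* and applied, with those training
   coefficients, to both training and held-out rows.  Residualization
   precedes model fitting; no standardization step is interposed (trees are
   scale-invariant).  An unseen categorical level at apply time is an error,
   never a silent zero-encoding.  The `ukbb-like` preset omits age, since in
   an age-group contrast age is the label.
3. **Models.**  Three tree-ensemble architectures behind one protocol:
   a bagged voting forest (in-repo CART with Gini splits, bootstrap rows,
   `sqrt(p)` feature subsampling per split, average-probability combine);
   sequential gradient boosting with logistic loss (squared-error regression
   trees on the negative gradient `y - p`, one Newton step per leaf —
   `sum(g)/sum(p(1-p))` — learning rate folded into stored leaf values,
   additive-margin combine); and extremely randomized trees via
   scikit-learn as the third architecture through the pluggable predict
   interface.  Any fitted scikit-learn tree model can be exported to the
   JSON tree schema (feature, threshold, children, leaf value, cover) and
   attributed identically.
4. **Evaluation.**  Repeated stratified 10-fold cross-validation;
   accuracy, sensitivity, specificity, F1 from the confusion counts, AUC as
   the Mann–Whitney rank statistic.  Architectures are compared with the
   corrected resampled t-test (variance factor `1/n + n_test/n_train`),
   which accounts for the overlap of training sets across folds.
5. **Attribution.**  Held-out rows of every fold are attributed with the
   path-dependent tree Shapley algorithm (below).  Per-feature importance
   is the mean |phi| pooled over all held-out attributions across folds and
   repetitions — the ordering used by standard SHAP summary plots.  The
   direction sign of a top feature is the sign of the Spearman correlation
   between feature value and phi (rank-based for robustness to heavy
   tails): +1 means higher connectivity pushes the model toward class 1.
6. **Consistency.**  Top-k sets (k = 20 by default, configurable) are
   compared across architectures by exact set arithmetic: pairwise and
   all-model intersection counts and the percentage of a model's top-k
   shared with at least one other model.  Features map to domain pairs via
   the atlas; a between-domain feature increments both endpoint domains.

## Shapley attribution

The Shapley value of feature `i` at instance `x` is the average, over all
feature orderings, of the change in a value function `v(S)` when `i` joins
coalition `S`.  Four routes are implemented:

* **Exact enumeration** (`exact_shapley`) uses an *interventional* value
  function: features in `S` are fixed to `x`, the rest are replaced by rows
  of an explicit background set and averaged.  Interventional
  marginalization was chosen over conditional because it is directly
  checkable by enumeration, and the background is always the training rows
  of the current fold (never test rows), so attributions cannot leak
  held-out information.  Exponential cost, capped at 16 features; it is the
  oracle the other routes are tested against.
* **Permutation sampling** (`sampling_shapley`) is the unbiased estimator of
  the same value with Monte-Carlo standard errors; each sampled order
  contributes one marginal-contribution sample per feature.
* **Tree-path algorithm** (`tree_shapley`) computes, in polynomial time per
  tree, the Shapley values of the path-dependent game in which absent
  features are marginalized down the tree using per-node training cover
  counts.  The implementation walks each node once, maintaining the
  coalition-size weight polynomial (extend/unwind); the bookkeeping is
  vectorized across explained rows, which share the path's feature sequence
  and cover ratios and differ only in hot/cold child assignment.
  Attributions are additive over trees, live in margin (log-odds) units for
  boosted ensembles and probability units for voting forests, and satisfy
  local accuracy exactly: `base_value + sum(phi)` equals the model output.
  Correctness is established by property tests against brute-force
  coalition enumeration on random trees (including repeated features along
  a path) and by exact local-accuracy checks on fitted ensembles.
* **Pairwise interaction index** (`interaction_value`): the
  coalition-weighted average of
  `f(S+{i,j}) - f(S+{i}) - f(S+{j}) + f(S)` with weight
  `|S|!(M-|S|-2)!/(2(M-1)!)`, symmetric in `(i, j)` and zero for additive
  models.  Per-feature values (not the pairwise index) drive all rankings;
  the interaction index is a separate diagnostic.

## Synthetic cohorts

`generate_features` emulates a two-class case-control feature table at the
dimensions of the motivating clinical study: 151 class-1 ("patient-like")
and 160 class-2 ("control-like") samples with 1378 features.  Baseline
features are i.i.d. standard normal per feature; the normal baseline makes
the expected class-mean gap at a planted feature exactly `2 * effect_delta`
and so directly testable.  Two contiguous blocks of 20 features each
(indices 100–119 and 700–719) are shifted `+delta` in class 1 and `-delta`
in class 2, `delta = 0.8` by default — strong enough that recovery is
expected, not so strong that every configuration saturates.  Demographic
covariates (age ~ N(37, 11) clipped to 18–65, sex ~ 3:1, seven sites) are
generated so the confound machinery runs under realistic cardinalities;
they carry no planted effect on the features.  Ground truth (indices and
directions) is written to a separate file so a model can never see it.

`generate_timecourses` plants effects one level earlier: a shared
unit-variance latent factor added with loading `lambda` to both components
of a pair in one class induces correlation `lambda^2 / (1 + lambda^2) < 1`
at that pair — bounded by construction — letting the full time-course →
FNC → classification → attribution path be exercised synthetically.

What the generator does **not** emulate: temporal autocorrelation and
hemodynamic spectra, correlation structure among the 1378 features (real
FNC vectors come from a common 53 x 53 PSD matrix), site- or age-linked
feature shifts, or heavy-tailed motion artifacts.  Passing recovery tests
therefore show that the protocol finds localized mean shifts at clinical
sample sizes; they do not certify performance under correlated or
confounded real-world noise.

## Validation experiments

`validate.recovery_run` is the package's acceptance harness: generate the
default cohort at a seed, run 5 repetitions of stratified 10-fold CV with
confound residualization, pool held-out attributions, and score the top-40
against the 40 planted features.  Both in-repo architectures recover the
planted blocks essentially completely (recall@40 = 1.0 across seeds in the
shipped runs) with cross-validated accuracy near 0.99 — consistent with a
2 x 0.8 SD mean gap at 40 of 1378 features being an easy learning problem.
`validate.null_recall` repeats the experiment with `delta = 0`: mean
recall@20 over 20 seeds must lie inside the 95% interval implied by drawing
20 of 1378 features uniformly at random (chance recall ~ 0.0145).

## Numerical and design choices

* **Split search**: candidate thresholds are midpoints between consecutive
  distinct sorted values; equal-gain ties resolve to the lowest feature
  index, then the lowest threshold, so fits are bit-reproducible.  A
  zero-gain split is still taken when a valid candidate exists (standard
  CART behaviour; enables XOR-like interactions), with pure-node, depth,
  and minimum-size stopping rules.
* **Desk-scale defaults**: forest 50 trees (depth cap 90, min-split 5,
  min-leaf 2 — the deep-tree regime of the clinical protocol, at a tree
  count sized for repeated refitting inside the validation loops; the
  200-tree clinical preset ships as `models.FBIRN_FOREST`); boosting 30
  rounds, learning rate 0.1, depth 3, 25% feature subsampling per round.
  The subsampling both regularizes and spreads splits across correlated
  planted features, which is what pooled attribution rankings measure.
* **Randomness**: every run derives all randomness (fold plans, bootstrap,
  feature subsampling, permutation sampling) from one root seed through
  named `SeedSequence` substreams, so components are independently
  reproducible and two same-seed runs produce identical artifacts.
* **Degenerate inputs**: all-one-class nodes become leaves (not errors);
  an all-one-class *dataset* yields a single-leaf tree predicting that
  class with probability 1.  Empty sensitivity/specificity/F1 denominators
  are reported as missing (NaN), never as 0.  Zero-variance features are
  rejected at FNC computation; constant features elsewhere are simply
  absorbed by the intercept during residualization.
* **Aggregation ambiguity**: mean ± SD summaries are emitted both pooled
  over all folds of all repetitions and per repetition, labeled, since
  either convention is defensible.

## Known limitations

* The path-dependent tree game differs from interventional marginalization
  when features are strongly dependent; both are provided, but the pipeline
  rankings use the tree game (they coincide for stumps and independent
  features).
* The permutation estimator at 1378 features needs many permutations for
  tight per-feature errors; the pipeline avoids it by using the tree route
  for all ranking work.
* The hyperparameter search of the original protocol (randomized/grid with
  an inner 5-fold loop) is available in spirit through `model_params`
  presets rather than re-implemented as an automated inner loop; the
  shipped defaults are the searched values of the clinical study where
  stated, desk-scaled where not.
* Brain-surface rendering is out of scope; edge lists and beeswarm tables
  are exported as plain TSV for external plotting tools.
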
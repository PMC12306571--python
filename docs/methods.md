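# Methods

## Model

The package assumes the treatment-effect linear decomposition: the CATE
τ(x) = E[τᵢ | Xᵢ = x] equals τ̄ + Σₘ αₘ rₘ(x), where each rₘ is a 0/1
decision rule (a conjunction of threshold conditions on covariates), τ̄ is
the intercept of the decomposition and αₘ is the additive average
treatment effect (AATE) of subgroup m. Identification rests on the usual
observational assumptions — unconfoundedness given X, overlap, and
consistency — inherited from whichever individual-effect estimator feeds
the decomposition. Note that the intercept τ̄ equals the population ATE
only when no rule is active; with planted rules it is the baseline effect
for units outside every discovered subgroup, and the sample ATE can be
recovered as the support-weighted sum of the decomposition.

Honest splitting: the sample is partitioned at random once, discovery
(default 50%, `ratio_dis`) never touching inference. Rule discovery is a
selection event; estimating the selected coefficients on data that did not
participate in selection removes the winner's-curse bias.

## Individual effect estimation

The regression target in both stages is a vector of individual treatment
effect estimates τ̂ᵢ:

* **aipw** (default): cross-fitted propensity scores ê(x) and arm-wise
  outcome regressions m̂₀, m̂₁ (K = 2 folds), combined into the
  doubly-robust pseudo-outcome
  τ̂ᵢ = m̂₁ − m̂₀ + zᵢ(yᵢ−m̂₁)/ê − (1−zᵢ)(yᵢ−m̂₀)/(1−ê).
  Cross-fitting keeps each unit's nuisance prediction out of its own
  training data; ê is clipped to [0.01, 0.99] (`clip_eps`).
* **slearner / tlearner / xlearner**: the standard meta-learner
  constructions; the X-learner weights its two imputed-effect regressions
  by ê(x).
* **user-supplied ite**: bypasses all nuisance fitting in both stages.

Learners are named registry entries ("linear", "logistic", "gbm", "rf",
"constant"; default "gbm" = scikit-learn gradient boosting) or any
scikit-learn-style estimator instance. Binary outcomes are detected and
routed to probability-predicting classifiers.

## Discovery

Gradient-boosted regression trees (default `ntrees=20`, `max_depth=3`,
`node_size=20`, subsample 0.7 per tree for path diversity) are fit to τ̂
on the discovery half. Every root-to-node path — internal nodes included,
to maximize the explored pattern space — becomes a candidate rule.
Conditions are canonicalized (per-variable interval intersection, sorted,
binary-covariate thresholds snapped to 0.5); duplicates are merged and
empty regions discarded.

Candidates are then simplified and thinned:

* **Decay pruning** (`t_decay=0.025`): greedy backward elimination — drop
  whichever condition least degrades the rule's two-group-means MSE on τ̂
  while the relative error increase stays below `t_decay`. We deliberately
  consider every condition position, not only the deepest: boosted trees
  occasionally root a path on an irrelevant variable, and a
  "junk ∧ true-rule" shadow that survives pruning later splits
  stability-selection votes with its parent rule.
* **Support filter** (`t_ext=0.025`): rules covering < 2.5% or > 97.5% of
  the sample are uninformative or unstable and are removed.
* **Correlation filter** (`t_corr=1`): scanning in importance order, a
  rule whose indicator correlates with an already retained rule at
  |ρ| ≥ t_corr is dropped; at the default 1 this removes only exact
  duplicates and complements.
* **Cap** (`max_rules=100`): keep the most important rules. Importance is
  the absolute MSE reduction of the rule's two-group-means predictor over
  the global mean; exact ties (always the case for a rule and its
  complement) break toward shorter rules, then toward "feature present"
  (>) conditions — a pure representation choice, since a complement
  carries identical information with flipped sign — then lexicographic
  key.

## Stability selection

Rules enter the final model only if an L1-penalized regression of τ̂ on
the rule matrix selects them in at least a `cutoff` (0.9) fraction of `B`
(50) subsamples of fraction `subsample` (0.05) drawn without replacement.
Columns are standardized within each subsample.

* **vanilla**: per-subsample sparsity q = ⌈2√M⌉ along the LARS path. The
  factor 2 gives generous headroom over a plausibly sparse truth: with
  q ≈ √M, correlated candidate variants can crowd true rules out of the
  active set on small subsamples and depress their selection frequency,
  while pure-noise columns still fall far short of the 0.9 cutoff. We
  also evaluated a per-subsample cross-validated penalty (equivalent
  selections, ~15× slower) and BIC/EBIC on the path (degenerate when the
  subsample is near-saturated, p ≈ n).
* **error_control**: q = ⌈√(pfer·(2·cutoff−1)·M)⌉ from the
  stability-selection per-family error bound E(V) ≤ q²/((2c−1)M), so
  `pfer` caps the expected number of false selections.
* **no**: a single LASSO on the full discovery half with a
  cross-validated penalty (deterministic, unshuffled folds).

## Inference

On the inference half, τ̂ is regressed by OLS on [1, R] for the selected
rules R (collinear columns dropped later-first with a warning; rules
constant on the inference half are dropped). Uncertainty comes from a
row-resampling bootstrap (default `n_boot=200`, independent of the
stability-selection B): percentile intervals at level 1−α (α = 0.05, i.e.
95% CIs) and two-sided p-values from the normal approximation with the
bootstrap standard error. Rank-deficient bootstrap replicates are redrawn
up to 10 times, then skipped with a warning. Rules with p > `t_pvalue`
(0.05) are dropped — all offenders at once — and the model refit and
re-bootstrapped until every survivor passes; removing one rule shifts the
others' estimates, hence the iteration.

Prediction on new covariates evaluates the fitted decomposition
τ̂(x) = τ̄ + Σ αₘ rₘ(x) exactly.

## Synthetic data generator

The generator emulates a randomized or confounded observational study
whose CATE is exactly a known sparse rule decomposition:

* Covariates: latent exchangeable-correlation Gaussians (one-factor
  construction, parameter `rho`); binary covariates threshold at 0
  (marginal Bernoulli(0.5)), continuous ones map through the standard
  normal CDF onto [0, 1].
* Rule template (first `n_rules` used): (x1∧x2, +e), (x5∧x6, −e),
  (x4, +e), (x5∧x7∧x8, −e) with e = `effect_size`; iteᵢ is the exact sum
  of satisfied contributions.
* Treatment: Bernoulli with e(x) = 0.5 ("no" confounding),
  logistic(−1 + x1 + x2) ("lin"), or logistic(−1 + x1·x2 + x3)
  ("nonlin").
* Outcome: y = b(X) + z·ite + ε with b(X) = x1 + x2 + x3 and ε ~ N(0, 1).
  The unit-coefficient linear baseline overlaps the confounding variables
  (so "lin"/"nonlin" genuinely confound) and the unit noise scale keeps
  the default effect sizes comfortably detectable at n in the low
  thousands. Binary outcomes threshold the latent y at its median.

What the generator does *not* emulate: non-additive effect surfaces that
no sparse rule set represents, heavy-tailed or heteroscedastic noise,
missing data, measurement error in covariates, and treatment effects that
vary continuously within a subgroup. Passing tests therefore demonstrate
correct mechanics and calibrated inference *under the decomposition
assumption*, not robustness to its violation.

## Numerical choices and degenerate inputs

* One top-level seed; per-stage streams derived through fixed
  `SeedSequence` codes, so supplying `ite` (which skips nuisance fitting)
  does not shift any downstream stream — identical inputs give
  bit-identical results either way.
* A constant τ̂ in discovery produces a split-free ensemble and an
  ATE-only model (with a warning), not an error; a subsample with < 10
  rows or < 2 distinct τ̂ values aborts stability selection with a clear
  message.
* Zero selected rules yields a valid ATE-only decomposition.
* LASSO support uses a 1e-10 coefficient cutoff; decay pruning guards its
  denominator at 1e-6; frequency/cutoff comparisons tolerate 1e-12.
* Missing values are rejected with row/column diagnostics, never imputed.
* `offset` is accepted and echoed in the configuration but not consumed.

## Problem sizes

The validation suite works at n = 2000 with two planted rules of
magnitude 5 (20 replicates for recovery, 100 for interval coverage and
for the pure-noise selection nulls), and the bundled simulation study in
`scripts/acceptance.py` uses the same design — sizes at which the
planted effects are strongly identified while a full run of the suite
stays in the minutes range on a single core.

## Known limitations

* Rules are axis-aligned conjunctions; obliquely separated subgroups are
  approximated, not represented.
* Percentile-bootstrap p-values are approximate in small inference
  samples; coverage was validated at n/2 = 1000 inference rows.
* The intercept-as-baseline reading of τ̄ (see Model) differs from the
  population ATE whenever rules have positive support.
* Internal causal-forest / BART effect estimators are not implemented;
  they plug in through the user-supplied `ite` path.
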
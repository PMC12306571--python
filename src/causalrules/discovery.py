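"""Candidate rule generation: fit-the-fit tree ensembles and rule filtering.

The discovery step fits an ensemble of gradient-boosted regression trees to
the IATE estimates tau_hat ("fit-the-fit"), turns every root-to-node path
of every tree into a candidate decision rule, then simplifies and thins the
candidate set:

* condition-decay pruning drops trailing conditions that barely change the
  rule's ability to explain tau_hat (threshold ``t_decay``);
* extreme-support rules (support < t_ext or > 1 - t_ext) are removed;
* near-duplicate rules (indicator correlation >= t_corr with an already
  retained rule) are removed, scanning in importance order;
* at most ``max_rules`` rules survive, ranked by importance.

Rule importance is the absolute reduction in mean squared error achieved by
predicting tau_hat with the rule's two group means instead of the global
mean; ties break toward shorter rules, then lexicographic key.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from .rules import (
    Condition,
    ContradictoryRuleError,
    DecisionRule,
)

_DECAY_EPS = 1e-6


def fit_tree_ensemble(
    X: np.ndarray,
    tau_hat: np.ndarray,
    ntrees: int = 20,
    max_depth: int = 3,
    node_size: int = 20,
    seed: Optional[int] = None,
) -> GradientBoostingRegressor:
    """Gradient-boosted regression trees on (X, tau_hat).

    A constant tau_hat yields an ensemble of stumps with no splits (hence
    zero candidate rules), not an error.
    """
    if ntrees < 1 or max_depth < 1 or node_size < 1:
        raise ValueError("ntrees, max_depth and node_size must all be >= 1")
    model = GradientBoostingRegressor(
        n_estimators=ntrees,
        max_depth=max_depth,
        min_samples_leaf=node_size,
        learning_rate=0.1,
        subsample=0.7,
        random_state=seed,
    )
    model.fit(np.asarray(X, dtype=float), np.asarray(tau_hat, dtype=float))
    return model


def _binary_columns(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.array([set(np.unique(X[:, j])) <= {0.0, 1.0} for j in range(X.shape[1])])


def extract_candidate_rules(
    ensemble: GradientBoostingRegressor,
    binary_mask: Optional[np.ndarray] = None,
) -> list[DecisionRule]:
    """Every root-to-node path (internal and leaf) of every tree as a rule.

    Thresholds on binary covariates are snapped to 0.5.  Conditions are
    canonicalized (per-variable interval intersection) and exact duplicates
    removed by canonical key; contradictory conjunctions are dropped.
    """
    seen: dict[str, DecisionRule] = {}

    def snap(var: int, threshold: float) -> float:
        if binary_mask is not None and var < len(binary_mask) and binary_mask[var]:
            return 0.5
        return float(threshold)

    def walk(tree, node: int, prefix: list[Condition]) -> None:
        if prefix:
            try:
                rule = DecisionRule(tuple(prefix))
            except ContradictoryRuleError:
                rule = None
            if rule is not None:
                seen.setdefault(rule.canonical_key, rule)
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:  # leaf
            return
        var = int(tree.feature[node])
        t = snap(var, tree.threshold[node])
        walk(tree, left, prefix + [Condition(var, "le", t)])
        walk(tree, right, prefix + [Condition(var, "gt", t)])

    for est in np.asarray(ensemble.estimators_).ravel():
        walk(est.tree_, 0, [])
    return list(seen.values())


def _rule_mse(indicator: np.ndarray, tau: np.ndarray) -> float:
    """MSE of predicting tau by the rule's two group means."""
    inside = indicator > 0.5
    pred = np.empty_like(tau)
    for mask in (inside, ~inside):
        pred[mask] = tau[mask].mean() if mask.any() else 0.0
    return float(np.mean((tau - pred) ** 2))


def rule_importance(rule: DecisionRule, X: np.ndarray, tau_hat: np.ndarray) -> float:
    """Absolute MSE reduction of the two-group-means predictor vs the global mean."""
    tau = np.asarray(tau_hat, dtype=float)
    base = float(np.mean((tau - tau.mean()) ** 2))
    return base - _rule_mse(rule.evaluate(X), tau)


def prune_rule_decay(
    rule: DecisionRule,
    X: np.ndarray,
    tau_hat: np.ndarray,
    t_decay: float = 0.025,
) -> DecisionRule:
    """Greedy backward elimination of conditions that barely help the fit.

    At each step the condition whose removal least degrades the rule's
    two-group-means MSE is dropped, provided the relative increase
    (err_pruned - err_full) / max(err_full, 1e-6) stays below ``t_decay``.
    Position-independent: an irrelevant condition is removed wherever the
    tree path placed it.  Stops at one condition or when every removal
    costs at least ``t_decay``.
    """
    tau = np.asarray(tau_hat, dtype=float)
    while rule.depth > 1:
        err_full = _rule_mse(rule.evaluate(X), tau)
        best: DecisionRule | None = None
        best_err = np.inf
        for i in range(rule.depth):
            conds = rule.conditions[:i] + rule.conditions[i + 1:]
            candidate = DecisionRule(conds)
            err = _rule_mse(candidate.evaluate(X), tau)
            if err < best_err:
                best, best_err = candidate, err
        if best is not None and (
            (best_err - err_full) / max(err_full, _DECAY_EPS) < t_decay
        ):
            rule = best
        else:
            break
    return rule


def _importance_order(
    rules: Sequence[DecisionRule], importance: np.ndarray
) -> np.ndarray:
    # exact importance ties (notably a rule and its complement) break toward
    # shorter rules, then "feature present" (>) conditions, then the key
    def n_le(r: DecisionRule) -> int:
        return sum(c.op == "le" for c in r.conditions)

    keys = [(-importance[i], rules[i].depth, n_le(rules[i]), rules[i].canonical_key)
            for i in range(len(rules))]
    return np.array(sorted(range(len(rules)), key=keys.__getitem__), dtype=int)


def filter_rules(
    rules: Sequence[DecisionRule],
    X: np.ndarray,
    t_ext: float = 0.025,
    t_corr: float = 1.0,
    max_rules: int = 100,
    importance: Optional[np.ndarray] = None,
    tau_hat: Optional[np.ndarray] = None,
) -> list[DecisionRule]:
    """Support, correlation and count filters on the candidate set.

    (i) drop rules with support < t_ext or > 1 - t_ext; (ii) scanning in
    importance order, drop any rule whose indicator correlates in absolute
    value >= t_corr with a retained rule's indicator (t_corr = 1 keeps
    everything except exact duplicates/complements); (iii) keep the top
    ``max_rules`` by importance.  Importance may be supplied directly or
    computed from ``tau_hat``.
    """
    if not (0 <= t_ext < 0.5):
        raise ValueError("t_ext must lie in [0, 0.5)")
    if not (0 < t_corr <= 1):
        raise ValueError("t_corr must lie in (0, 1]")
    if len(rules) == 0:
        return []
    if importance is None:
        if tau_hat is None:
            raise ValueError("provide either importance or tau_hat")
        importance = np.array([rule_importance(r, X, tau_hat) for r in rules])
    importance = np.asarray(importance, dtype=float)

    indicators = np.column_stack([r.evaluate(X) for r in rules])
    support = indicators.mean(axis=0)
    ok = (support >= t_ext) & (support <= 1 - t_ext) & (support > 0) & (support < 1)

    kept: list[int] = []
    for i in _importance_order(rules, importance):
        if not ok[i]:
            continue
        col = indicators[:, i]
        redundant = False
        for j in kept:
            c = np.corrcoef(col, indicators[:, j])[0, 1]
            if abs(c) >= t_corr - 1e-12:
                redundant = True
                break
        if not redundant:
            kept.append(i)
        if len(kept) == max_rules:
            break
    return [rules[i] for i in kept]
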
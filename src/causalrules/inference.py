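"""Honest inference: ATE/AATE estimation with bootstrap uncertainty.

On the held-out inference sample, the IATE estimates are regressed by
ordinary least squares on [1, R] where R is the indicator matrix of the
selected rules: the intercept estimates the ATE (tau_bar) and the slopes
the additive average treatment effects (AATEs, alpha_m).  Percentile
bootstrap confidence intervals and normal-approximation p-values (from the
bootstrap standard error) quantify uncertainty; rules failing a p-value
threshold are pruned and the model refit until all survivors pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .rules import DecisionRule, RuleMatrix, build_rule_matrix


class DegenerateDesignError(ValueError):
    pass


@dataclass
class CATEDecomposition:
    """Fitted linear CATE decomposition: tau(x) = ate + sum_m aate_m r_m(x)."""

    ate: float
    rules: list[DecisionRule]
    aate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    alpha: float = 0.05
    ate_ci: tuple[float, float] = (math.nan, math.nan)
    ate_pvalue: float = math.nan
    M_candidates: int = 0
    M_selected: int = 0
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.rules)
        if not (len(self.aate) == len(self.ci_low) == len(self.ci_high)
                == len(self.pvalues) == m):
            raise ValueError("decomposition fields must align with the rule list")

    @property
    def M_final(self) -> int:
        return len(self.rules)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict_cate(self, X_new)


def honest_split(
    n: int, ratio_dis: float = 0.5, seed: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split into discovery / inference indices."""
    if not (0 < ratio_dis < 1):
        raise ValueError("ratio_dis must lie in (0, 1)")
    n_dis = math.ceil(ratio_dis * n)
    if n_dis == 0 or n_dis == n:
        raise ValueError(
            f"ratio_dis={ratio_dis} leaves an empty discovery or inference sample"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_dis]), np.sort(perm[n_dis:])


def _design(R: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(R.shape[0]), R])


def _full_rank_columns(R: np.ndarray) -> list[int]:
    """Greedily keep earlier columns so that [1, R_kept] has full rank."""
    kept: list[int] = []
    base = np.ones((R.shape[0], 1))
    for j in range(R.shape[1]):
        trial = np.column_stack([base, R[:, kept + [j]]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(j)
    return kept


def fit_decomposition(
    R: RuleMatrix | np.ndarray, tau_hat: np.ndarray
) -> tuple[float, np.ndarray]:
    """OLS of tau_hat on [1, R]: intercept = ATE, slopes = AATEs."""
    mat = R.indicators if isinstance(R, RuleMatrix) else np.asarray(R, dtype=float)
    tau = np.asarray(tau_hat, dtype=float)
    X = _design(mat)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            "rule matrix is rank deficient with intercept; drop collinear rules"
        )
    beta, *_ = np.linalg.lstsq(X, tau, rcond=None)
    return float(beta[0]), beta[1:]


def drop_collinear(
    R: RuleMatrix, warn: bool = True
) -> tuple[RuleMatrix, list[int]]:
    """Drop later (lower-importance) rules until [1, R] has full rank."""
    kept = _full_rank_columns(R.indicators)
    if len(kept) < R.M and warn:
        dropped = [R.rules[j].canonical_key for j in range(R.M) if j not in kept]
        warnings.warn(f"dropping collinear rules: {dropped}")
    return RuleMatrix(R.indicators[:, kept], [R.rules[j] for j in kept]), kept


def bootstrap_inference(
    R: RuleMatrix | np.ndarray,
    tau_hat: np.ndarray,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap CIs and normal-approximation p-values.

    Returns (ci_low, ci_high, pvalues, boot_coefs) for the full coefficient
    vector including the intercept (row 0 of each).
    """
    mat = R.indicators if isinstance(R, RuleMatrix) else np.asarray(R, dtype=float)
    tau = np.asarray(tau_hat, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    n = len(tau)
    ate, aate = fit_decomposition(mat, tau)
    point = np.concatenate([[ate], aate])

    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                a, b = fit_decomposition(mat[idx], tau[idx])
            except DegenerateDesignError:
                continue
            draws.append(np.concatenate([[a], b]))
            break
        else:
            warnings.warn("skipping a rank-deficient bootstrap replicate")
    boot = np.asarray(draws)
    ci_low = np.percentile(boot, 100 * alpha / 2, axis=0)
    ci_high = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    se = boot.std(axis=0, ddof=1)
    pvalues = np.where(
        se > 1e-12,
        2 * norm.sf(np.abs(point) / np.where(se > 1e-12, se, 1.0)),
        np.where(np.abs(point) > 1e-12, 0.0, 1.0),
    )
    return ci_low, ci_high, pvalues, boot


def fit_and_infer(
    R: RuleMatrix,
    tau_hat: np.ndarray,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    M_candidates: int = 0,
    M_selected: int = 0,
    config: Optional[dict[str, Any]] = None,
) -> CATEDecomposition:
    """OLS point estimates plus bootstrap uncertainty, as a result object."""
    ate, aate = fit_decomposition(R, tau_hat)
    lo, hi, pv, _ = bootstrap_inference(R, tau_hat, n_boot, alpha, seed)
    return CATEDecomposition(
        ate=ate,
        rules=list(R.rules),
        aate=aate,
        ci_low=lo[1:],
        ci_high=hi[1:],
        pvalues=pv[1:],
        alpha=alpha,
        ate_ci=(float(lo[0]), float(hi[0])),
        ate_pvalue=float(pv[0]),
        M_candidates=M_candidates,
        M_selected=M_selected,
        config=dict(config or {}),
    )


def prune_by_pvalue(
    model: CATEDecomposition,
    t_pvalue: float,
    R: RuleMatrix,
    tau_hat: np.ndarray,
    n_boot: int = 200,
    seed: Optional[int] = None,
) -> CATEDecomposition:
    """Drop rules with p-value > t_pvalue, refit, iterate to a fixed point."""
    if not (0 < t_pvalue <= 1):
        raise ValueError("t_pvalue must lie in (0, 1]")
    current_R, current = R, model
    while current.M_final > 0:
        keep = np.flatnonzero(np.asarray(current.pvalues) <= t_pvalue)
        if len(keep) == current.M_final:
            break
        current_R = RuleMatrix(
            current_R.indicators[:, keep], [current_R.rules[j] for j in keep]
        )
        if current_R.M == 0:
            ate, _ = fit_decomposition(current_R, tau_hat)
            lo, hi, pv, _ = bootstrap_inference(
                current_R, tau_hat, n_boot, model.alpha, seed
            )
            return CATEDecomposition(
                ate=ate, rules=[], aate=np.empty(0), ci_low=np.empty(0),
                ci_high=np.empty(0), pvalues=np.empty(0), alpha=model.alpha,
                ate_ci=(float(lo[0]), float(hi[0])), ate_pvalue=float(pv[0]),
                M_candidates=model.M_candidates, M_selected=model.M_selected,
                config=model.config,
            )
        current = fit_and_infer(
            current_R, tau_hat, n_boot, model.alpha, seed,
            M_candidates=model.M_candidates, M_selected=model.M_selected,
            config=model.config,
        )
    return current


def predict_cate(model: CATEDecomposition, X_new: np.ndarray) -> np.ndarray:
    """CATE prediction ate + sum_m aate_m r_m(x) per row of X_new."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2:
        raise ValueError("X_new must be a 2-d matrix")
    out = np.full(X_new.shape[0], model.ate, dtype=float)
    for coef, rule in zip(model.aate, model.rules):
        out += coef * rule.evaluate(X_new)
    return out


def forced_rule_inference(
    rules: Sequence[DecisionRule],
    X: np.ndarray,
    tau_hat: np.ndarray,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> CATEDecomposition:
    """Inference with a user-imposed selected rule set (no discovery)."""
    R = build_rule_matrix(rules, X)
    return fit_and_infer(R, tau_hat, n_boot=n_boot, alpha=alpha, seed=seed,
                         M_candidates=len(rules), M_selected=len(rules))
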
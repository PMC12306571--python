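"""Full pipeline orchestration: the causal rule ensemble fit.

``cre_fit`` runs honest splitting, IATE estimation, tree-based rule
discovery, stability selection and bootstrap inference end to end and
returns a :class:`CREResult` holding the rule counts at each stage, the
final rules, and the CATE decomposition table with uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .discovery import (
    extract_candidate_rules,
    filter_rules,
    fit_tree_ensemble,
    prune_rule_decay,
    rule_importance,
    _binary_columns,
)
from .iate import estimate_iate
from .inference import (
    CATEDecomposition,
    drop_collinear,
    fit_and_infer,
    honest_split,
    predict_cate,
    prune_by_pvalue,
)
from .rules import DecisionRule, RuleMatrix, build_rule_matrix
from .selection import stability_selection

logger = logging.getLogger("causalrules")


@dataclass
class CREResult:
    """The fitted causal rule ensemble."""

    M: dict[str, int]
    rules: list[str]
    decomposition: CATEDecomposition
    config: dict[str, Any]
    feature_names: Optional[list[str]] = None
    selection_frequencies: dict[str, float] = field(default_factory=dict)

    @property
    def ate(self) -> float:
        return self.decomposition.ate

    @property
    def cate_table(self) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(
            {
                "rule": [r.text(self.feature_names) for r in d.rules],
                "aate": np.asarray(d.aate, dtype=float),
                "ci_low": np.asarray(d.ci_low, dtype=float),
                "ci_high": np.asarray(d.ci_high, dtype=float),
                "pvalue": np.asarray(d.pvalues, dtype=float),
            }
        )

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """CATE prediction on a new covariate matrix."""
        X_new = _coerce_matrix(X_new, self.feature_names)
        return predict_cate(self.decomposition, X_new)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return summarize(self)


def _coerce_matrix(X: Any, feature_names: Optional[Sequence[str]]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing covariate columns: {missing}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise KeyError(
            f"expected {len(feature_names)} covariate columns, got {X.shape[1]}"
        )
    return X


def _validate_inputs(
    y: np.ndarray, z: np.ndarray, X: np.ndarray, ite: Optional[np.ndarray]
) -> None:
    n = len(y)
    if not (len(z) == n and X.shape[0] == n):
        raise ValueError("y, z and X must have aligned lengths")
    if ite is not None and len(ite) != n:
        raise ValueError("ite must align with y, z, X")
    if not np.isin(np.asarray(z, dtype=float), (0.0, 1.0)).all():
        raise ValueError("treatment vector z must be binary (0/1)")
    for name, arr in (("y", y), ("X", X)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains missing or non-finite values")


def cre_fit(
    y: np.ndarray,
    z: np.ndarray,
    X: Any,
    config: Optional[PipelineConfig | dict[str, Any]] = None,
    ite: Optional[np.ndarray] = None,
) -> CREResult:
    """Fit the causal rule ensemble on (y, z, X).

    When ``ite`` is supplied, internal IATE estimation is skipped in both
    the discovery and the inference step and the given vector is split
    alongside the data.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config.validate()

    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = _coerce_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if ite is not None:
        ite = np.asarray(ite, dtype=float)
    _validate_inputs(y, z, Xm, ite)
    n = len(y)

    dis, inf = honest_split(n, config.ratio_dis, config.stage_seed("split"))

    def tau_for(idx: np.ndarray, stage: str) -> np.ndarray:
        if ite is not None:
            return ite[idx]
        est = estimate_iate(
            Xm[idx], y[idx], z[idx],
            method=config.ite_method,
            learner_ps=config.learner_ps,
            learner_y=config.learner_y,
            clip_eps=config.clip_eps,
            n_folds=config.n_folds,
            seed=config.stage_seed(stage),
        )
        return est.tau_hat

    # ---- discovery -------------------------------------------------------
    tau_dis = tau_for(dis, "iate_discovery")
    X_dis = Xm[dis]
    if config.intervention_vars is not None:
        active = list(config.intervention_vars)
        X_tree = X_dis[:, active]
    else:
        active = list(range(Xm.shape[1]))
        X_tree = X_dis

    ensemble = fit_tree_ensemble(
        X_tree, tau_dis,
        ntrees=config.ntrees, max_depth=config.max_depth,
        node_size=config.node_size, seed=config.stage_seed("trees"),
    )
    raw = extract_candidate_rules(ensemble, binary_mask=_binary_columns(X_tree))
    raw = [_remap_rule(r, active) for r in raw]
    logger.info("discovery: %d raw candidate rules", len(raw))

    pruned: dict[str, DecisionRule] = {}
    for r in raw:
        rp = prune_rule_decay(r, X_dis, tau_dis, config.t_decay)
        pruned.setdefault(rp.canonical_key, rp)
    candidates = list(pruned.values())
    importance = np.array([rule_importance(r, X_dis, tau_dis) for r in candidates])
    filtered = filter_rules(
        candidates, X_dis,
        t_ext=config.t_ext, t_corr=config.t_corr,
        max_rules=config.max_rules, importance=importance,
    )
    logger.info("discovery: %d candidates after pruning/filtering", len(filtered))

    freqs: dict[str, float] = {}
    selected_rules: list[DecisionRule] = []
    if filtered:
        R_dis = build_rule_matrix(filtered, X_dis)
        sel = stability_selection(
            R_dis, tau_dis,
            mode=config.stability_selection, B=config.B,
            subsample=config.subsample, cutoff=config.cutoff,
            pfer=config.pfer, seed=config.stage_seed("stability"),
        )
        freqs = {
            filtered[j].canonical_key: float(f)
            for j, f in enumerate(sel.frequencies)
        }
        selected_rules = [filtered[j] for j in sel.selected]
    logger.info("selection: %d rules selected", len(selected_rules))

    # ---- inference -------------------------------------------------------
    tau_inf = tau_for(inf, "iate_inference")
    X_inf = Xm[inf]
    usable = []
    for r in selected_rules:
        col = r.evaluate(X_inf)
        if 0 < col.mean() < 1:
            usable.append(r)
        else:
            warnings.warn(
                f"rule {r.canonical_key!r} is constant on the inference sample; dropped"
            )
    if usable:
        R_inf, _ = drop_collinear(build_rule_matrix(usable, X_inf))
    else:
        R_inf = RuleMatrix(np.empty((len(inf), 0)), [])
    if R_inf.M == 0 and len(selected_rules) == 0:
        warnings.warn("no rules selected; returning an ATE-only decomposition")

    model = fit_and_infer(
        R_inf, tau_inf,
        n_boot=config.n_boot, alpha=config.alpha,
        seed=config.stage_seed("bootstrap"),
        M_candidates=len(filtered), M_selected=len(selected_rules),
        config=config.to_dict(),
    )
    model = prune_by_pvalue(
        model, config.t_pvalue, R_inf, tau_inf,
        n_boot=config.n_boot, seed=config.stage_seed("bootstrap"),
    )
    logger.info("inference: %d final rules, ATE=%.4g", model.M_final, model.ate)

    return CREResult(
        M={
            "candidates": len(filtered),
            "selected": len(selected_rules),
            "final": model.M_final,
        },
        rules=[r.text(feature_names) for r in model.rules],
        decomposition=model,
        config=config.to_dict(),
        feature_names=feature_names,
        selection_frequencies=freqs,
    )


def _remap_rule(rule: DecisionRule, active: list[int]) -> DecisionRule:
    """Map tree-local feature indices back to the full covariate space."""
    from .rules import Condition

    if active == list(range(len(active))):
        return rule
    conds = tuple(
        Condition(active[c.var], c.op, c.threshold) for c in rule.conditions
    )
    return DecisionRule(conds)


def summarize(result: CREResult) -> str:
    """Human-readable summary of the fitted decomposition."""
    if not isinstance(result, CREResult):
        raise TypeError("summarize expects a CREResult")
    d = result.decomposition
    level = int(round((1 - d.alpha) * 100))
    lines = [
        "Causal rule ensemble — CATE decomposition",
        "-" * 46,
        f"Rules: {result.M['candidates']} candidate(s) -> "
        f"{result.M['selected']} selected -> {result.M['final']} final",
        f"ATE: {d.ate:+.4f}  ({level}% CI [{d.ate_ci[0]:+.4f}, {d.ate_ci[1]:+.4f}])",
    ]
    if d.M_final == 0:
        lines.append("0 rules in the final decomposition (ATE-only model).")
    else:
        table = result.cate_table
        lines.append(
            f"{'rule':<32} {'aate':>9} {'ci_low':>9} {'ci_high':>9} {'pvalue':>9}"
        )
        for _, row in table.iterrows():
            lines.append(
                f"{row['rule']:<32} {row['aate']:>+9.4f} {row['ci_low']:>+9.4f} "
                f"{row['ci_high']:>+9.4f} {row['pvalue']:>9.4f}"
            )
    return "\n".join(lines)


def export_plot_data(result: CREResult) -> pd.DataFrame:
    """Rows (rule, aate, ci_low, ci_high) sorted by AATE descending.

    Ordered from the most vulnerable subgroup (highest AATE) down; ties
    break by rule text.  The ATE is attached as ``df.attrs['ate']`` for the
    plot header.
    """
    if not isinstance(result, CREResult):
        raise TypeError("export_plot_data expects a CREResult")
    df = result.cate_table[["rule", "aate", "ci_low", "ci_high"]].copy()
    df = df.sort_values(
        ["aate", "rule"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["ate"] = result.ate
    df.attrs["alpha"] = result.decomposition.alpha
    return df


def plot_decomposition(result: CREResult, ax=None):
    """Range bar plot of the AATE estimates with confidence intervals."""
    import matplotlib.pyplot as plt

    df = export_plot_data(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.6 * max(len(df), 2) + 1.2))
    ypos = np.arange(len(df))[::-1]
    err = np.vstack([df["aate"] - df["ci_low"], df["ci_high"] - df["aate"]])
    ax.errorbar(df["aate"], ypos, xerr=err, fmt="o", capsize=4)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["rule"])
    level = int(round((1 - df.attrs["alpha"]) * 100))
    ax.set_xlabel(f"AATE ({level}% CI)")
    ax.set_title(f"ATE = {df.attrs['ate']:+.3f}")
    return ax
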
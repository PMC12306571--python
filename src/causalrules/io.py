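"""Reading datasets from CSV and serializing results to JSON/CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from .inference import CATEDecomposition
from .pipeline import CREResult
from .rules import rule_from_text

PathLike = Union[str, Path]


class DatasetFormatError(ValueError):
    pass


def read_dataset(
    path: PathLike,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, Optional[np.ndarray]]:
    """Load (y, z, X[, ite]) from a headed CSV.

    Requires columns ``y`` and ``z``; an optional ``ite`` column carries
    user-supplied individual effect estimates; all remaining columns are
    covariates (names preserved).  Missing values are rejected with
    row/column diagnostics, never imputed.
    """
    df = pd.read_csv(path)
    for col in ("y", "z"):
        if col not in df.columns:
            raise DatasetFormatError(f"required column {col!r} missing from {path}")
    if df.isna().any().any():
        bad = [
            (int(i), str(c))
            for c in df.columns
            for i in df.index[df[c].isna()][:5]
        ]
        raise DatasetFormatError(f"missing values at (row, column): {bad[:10]}")
    z = df["z"].to_numpy(dtype=float)
    if not np.isin(z, (0.0, 1.0)).all():
        bad_rows = np.flatnonzero(~np.isin(z, (0.0, 1.0)))[:5]
        raise DatasetFormatError(
            f"z must be binary (0/1); offending rows: {bad_rows.tolist()}"
        )
    y = df["y"].to_numpy(dtype=float)
    ite = df["ite"].to_numpy(dtype=float) if "ite" in df.columns else None
    X = df.drop(columns=[c for c in ("y", "z", "ite") if c in df.columns])
    if X.shape[1] == 0:
        raise DatasetFormatError("no covariate columns found")
    try:
        X = X.astype(float)
    except ValueError as exc:
        raise DatasetFormatError(f"non-numeric covariate values: {exc}") from exc
    return y, z, X, ite


def write_dataset(path: PathLike, y, z, X, ite=None,
                  true_rules=None, true_aates=None) -> None:
    """Write a dataset CSV (columns y, z, x1..xp[, ite]) plus, when the
    ground truth is known, a JSON sidecar with true rules and AATEs."""
    X = np.asarray(X, dtype=float)
    cols = {"y": np.asarray(y, dtype=float), "z": np.asarray(z, dtype=float)}
    for j in range(X.shape[1]):
        cols[f"x{j + 1}"] = X[:, j]
    if ite is not None:
        cols["ite"] = np.asarray(ite, dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False)
    if true_rules is not None:
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps({
            "true_rules": [r.canonical_key for r in true_rules],
            "true_aates": list(np.asarray(true_aates, dtype=float)),
        }, indent=2))


def result_to_dict(result: CREResult) -> dict[str, Any]:
    d = result.decomposition
    return {
        "M": dict(result.M),
        "ate": d.ate,
        "ate_ci": list(d.ate_ci),
        "ate_pvalue": d.ate_pvalue,
        "alpha": d.alpha,
        "rules": [
            {
                "rule": r.canonical_key,
                "text": r.text(result.feature_names),
                "aate": float(a),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "pvalue": float(p),
            }
            for r, a, lo, hi, p in zip(d.rules, d.aate, d.ci_low, d.ci_high, d.pvalues)
        ],
        "selection_frequencies": dict(result.selection_frequencies),
        "feature_names": result.feature_names,
        "config": dict(result.config),
    }


def result_from_dict(payload: dict[str, Any]) -> CREResult:
    rules = [rule_from_text(r["rule"]) for r in payload["rules"]]
    d = CATEDecomposition(
        ate=float(payload["ate"]),
        rules=rules,
        aate=np.array([r["aate"] for r in payload["rules"]], dtype=float),
        ci_low=np.array([r["ci_low"] for r in payload["rules"]], dtype=float),
        ci_high=np.array([r["ci_high"] for r in payload["rules"]], dtype=float),
        pvalues=np.array([r["pvalue"] for r in payload["rules"]], dtype=float),
        alpha=float(payload["alpha"]),
        ate_ci=tuple(payload["ate_ci"]),
        ate_pvalue=float(payload["ate_pvalue"]),
        M_candidates=int(payload["M"]["candidates"]),
        M_selected=int(payload["M"]["selected"]),
        config=dict(payload["config"]),
    )
    return CREResult(
        M=dict(payload["M"]),
        rules=[r["text"] for r in payload["rules"]],
        decomposition=d,
        config=dict(payload["config"]),
        feature_names=payload.get("feature_names"),
        selection_frequencies=dict(payload.get("selection_frequencies", {})),
    )


def write_result(result: CREResult, path: PathLike) -> None:
    """Write the full result as JSON and the CATE table as a sibling CSV.

    The CSV carries one row per rule (rule, aate, ci_low, ci_high, pvalue);
    the ATE travels in the JSON and in the CSV header comment.
    """
    path = Path(path)
    path.write_text(json.dumps(result_to_dict(result), indent=2))
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w") as fh:
        fh.write(f"# ate={result.ate!r} alpha={result.decomposition.alpha!r}\n")
        result.cate_table.to_csv(fh, index=False)


def read_result(path: PathLike) -> CREResult:
    return result_from_dict(json.loads(Path(path).read_text()))
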
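"""LASSO-based stability selection of candidate rules.

Rules enter the final linear decomposition only if an L1-penalized
regression of tau_hat on the rule indicator matrix selects them in at
least a ``cutoff`` fraction of ``B`` random subsamples.  Three modes:

* ``"vanilla"`` — per-subsample sparsity q = ceil(2 sqrt(M)) along the
  LARS path (generous headroom over a sparse truth so that correlated
  candidates cannot split the votes); keep rules with selection frequency
  >= cutoff.
* ``"error_control"`` — q derived from the stability-selection per-family
  error bound E(V) <= q^2 / ((2 cutoff - 1) M), i.e.
  q = ceil(sqrt(pfer (2 cutoff - 1) M)); same frequency threshold.
* ``"no"`` — a single LASSO fit on the full data with a cross-validated
  penalty; frequencies are 0/1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, lars_path

from .rules import RuleMatrix

SELECTION_MODES = ("no", "vanilla", "error_control")


@dataclass
class SelectionResult:
    selected: list[int]
    frequencies: np.ndarray
    mode: str
    cutoff: float
    pfer: float
    B: int
    subsample: float


def _standardize(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns (standardized matrix, usable-column mask)."""
    mu = R.mean(axis=0)
    sd = R.std(axis=0)
    usable = sd > 0
    Z = np.zeros_like(R, dtype=float)
    Z[:, usable] = (R[:, usable] - mu[usable]) / sd[usable]
    return Z, usable


def lasso_support(
    R: Union[RuleMatrix, np.ndarray],
    tau_hat: np.ndarray,
    lam: Union[float, str] = "auto",
    q: Optional[int] = None,
) -> set[int]:
    """Indices with nonzero coefficient in the L1-penalized regression.

    Columns are standardized internally; with ``q`` given, the penalty is
    chosen on the LARS path as the first knot admitting at most ``q``
    active variables (taking as many as possible up to ``q``).
    """
    mat = R.indicators if isinstance(R, RuleMatrix) else np.asarray(R, dtype=float)
    tau = np.asarray(tau_hat, dtype=float)
    if mat.shape[1] == 0:
        return set()
    if isinstance(lam, (int, float)) and lam < 0:
        raise ValueError("lambda must be non-negative")
    Z, usable = _standardize(mat)
    yc = tau - tau.mean()
    cols = np.flatnonzero(usable)
    if len(cols) == 0:
        return set()
    Zu = Z[:, cols]

    if q is not None:
        with warnings.catch_warnings():
            # binary indicator columns are often nearly collinear on small
            # subsamples; LARS handles this by dropping regressors
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, _, coefs = lars_path(Zu, yc, method="lasso")
        counts = (coefs != 0).sum(axis=0)
        admissible = np.flatnonzero(counts <= q)
        knot = admissible[np.argmax(counts[admissible])]
        active = np.flatnonzero(coefs[:, knot])
        return {int(cols[i]) for i in active}

    if lam == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LassoCV(cv=min(5, len(yc)), alphas=50).fit(Zu, yc)
        coef = model.coef_
    else:
        model = Lasso(alpha=float(lam), max_iter=5000).fit(Zu, yc)
        coef = model.coef_
    return {int(cols[i]) for i in np.flatnonzero(np.abs(coef) > 1e-10)}


def pfer_sparsity(M: int, cutoff: float, pfer: float) -> int:
    """Per-subsample q from the per-family error bound E(V) <= q^2/((2c-1)M)."""
    if cutoff <= 0.5:
        raise ValueError("error_control needs cutoff > 0.5 (bound undefined)")
    return max(1, math.ceil(math.sqrt(pfer * (2 * cutoff - 1) * M)))


def stability_selection(
    R: Union[RuleMatrix, np.ndarray],
    tau_hat: np.ndarray,
    mode: str = "vanilla",
    B: int = 50,
    subsample: float = 0.05,
    cutoff: float = 0.9,
    pfer: float = 0.1,
    seed: Optional[int] = None,
) -> SelectionResult:
    """Select rules by selection frequency across B subsamples."""
    mat = R.indicators if isinstance(R, RuleMatrix) else np.asarray(R, dtype=float)
    tau = np.asarray(tau_hat, dtype=float)
    n, M = mat.shape
    if mode not in SELECTION_MODES:
        raise ValueError(f"mode must be one of {SELECTION_MODES}")
    if M == 0:
        return SelectionResult([], np.empty(0), mode, cutoff, pfer, B, subsample)

    if mode == "no":
        support = lasso_support(mat, tau, lam="auto")
        freq = np.zeros(M)
        freq[sorted(support)] = 1.0
        return SelectionResult(sorted(support), freq, mode, cutoff, pfer, B, subsample)

    if not (0.5 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0.5, 1]")
    if not (0 < subsample < 1):
        raise ValueError("subsample must lie in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    size = math.ceil(subsample * n)
    if size < 10:
        raise ValueError(
            f"subsample size {size} too small (needs >= 10 observations); "
            "raise `subsample` or supply more data"
        )

    if mode == "error_control":
        q = pfer_sparsity(M, cutoff, pfer)
    else:
        q = min(M, math.ceil(2 * math.sqrt(M)))
    rng = np.random.default_rng(seed)
    counts = np.zeros(M)
    for _ in range(B):
        idx = rng.choice(n, size=size, replace=False)
        if len(np.unique(tau[idx])) < 2:
            raise ValueError("subsample has fewer than 2 distinct tau_hat values")
        for j in lasso_support(mat[idx], tau[idx], q=q):
            counts[j] += 1
    freq = counts / B
    selected = sorted(int(i) for i in np.flatnonzero(freq >= cutoff - 1e-12))
    return SelectionResult(selected, freq, mode, cutoff, pfer, B, subsample)
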
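"""Individual average treatment effect (IATE) estimation.

Produces per-unit treatment effect estimates tau_hat_i from (y, z, X) via
pluggable meta-learners — the doubly-robust AIPW pseudo-outcome, or the
S-/T-/X-learner constructions — used as the regression target in both the
discovery and the inference step.  Nuisance models (propensity score and
outcome regressions) are cross-fitted in K folds so that each unit's
prediction comes from a model not trained on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional

import numpy as np
from sklearn.model_selection import KFold

from .learners import make_learner, predict_values

IATE_METHODS = ("aipw", "slearner", "tlearner", "xlearner")


class DegenerateDesignError(ValueError):
    """Raised when the treatment/control design cannot support estimation."""


@dataclass
class IATEEstimate:
    tau_hat: np.ndarray
    method: str
    ps_hat: Optional[np.ndarray] = None
    m0_hat: Optional[np.ndarray] = None
    m1_hat: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.tau_hat)):
            raise ValueError("tau_hat contains non-finite values")


def _check_binary_treatment(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("treatment vector z must be binary (0/1)")
    if z.min() == z.max():
        raise DegenerateDesignError("all units share one treatment arm")
    return z


def _folds(n: int, n_folds: int, seed: Optional[int]) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def estimate_propensity(
    X: np.ndarray,
    z: np.ndarray,
    learner: Any = "logistic",
    clip_eps: float = 0.01,
    n_folds: int = 2,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Cross-fitted propensity scores e_hat(x), clipped into [eps, 1-eps]."""
    X = np.asarray(X, dtype=float)
    z = _check_binary_treatment(z)
    if not (0 < clip_eps < 0.5):
        raise ValueError("clip_eps must lie in (0, 0.5)")
    ps = np.empty(len(z))
    for k, (train, test) in enumerate(_folds(len(z), n_folds, seed)):
        model = make_learner(learner, "classification",
                             random_state=None if seed is None else seed + k)
        model.fit(X[train], z[train])
        ps[test] = predict_values(model, X[test])
    return np.clip(ps, clip_eps, 1 - clip_eps)


def fit_outcome_models(
    X: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    learner: Any = "linear",
    n_folds: int = 2,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-fitted arm-specific outcome predictions (m0_hat, m1_hat)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    z = _check_binary_treatment(z)
    task = "classification" if set(np.unique(y)) <= {0.0, 1.0} else "regression"
    m0, m1 = np.empty(len(y)), np.empty(len(y))
    for k, (train, test) in enumerate(_folds(len(y), n_folds, seed)):
        for arm, out in ((0, m0), (1, m1)):
            mask = train[z[train] == arm]
            if len(mask) < 2:
                raise DegenerateDesignError(
                    f"too few observations in arm {arm} of a cross-fitting fold"
                )
            model = make_learner(learner, task,
                                 random_state=None if seed is None else seed + k)
            model.fit(X[mask], y[mask])
            out[test] = predict_values(model, X[test])
    return m0, m1


def pseudo_outcome_aipw(
    y: np.ndarray,
    z: np.ndarray,
    ps_hat: np.ndarray,
    m0_hat: np.ndarray,
    m1_hat: np.ndarray,
) -> np.ndarray:
    """Doubly-robust AIPW pseudo-outcome.

    tau_i = m1_i - m0_i + z_i (y_i - m1_i)/e_i - (1 - z_i)(y_i - m0_i)/(1 - e_i)
    """
    y, z = np.asarray(y, dtype=float), np.asarray(z, dtype=float)
    ps = np.asarray(ps_hat, dtype=float)
    m0, m1 = np.asarray(m0_hat, dtype=float), np.asarray(m1_hat, dtype=float)
    if not (len(y) == len(z) == len(ps) == len(m0) == len(m1)):
        raise ValueError("AIPW inputs must be aligned")
    if np.any(ps <= 0) or np.any(ps >= 1):
        raise ValueError("ps_hat must be strictly inside (0, 1); clip first")
    return m1 - m0 + z * (y - m1) / ps - (1 - z) * (y - m0) / (1 - ps)


def meta_learner_iate(
    X: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    method: str,
    learner_y: Any = "linear",
    ps_hat: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> IATEEstimate:
    """S-, T- or X-learner point estimates of the IATE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    z = _check_binary_treatment(z)
    task = "classification" if set(np.unique(y)) <= {0.0, 1.0} else "regression"

    if method == "slearner":
        model = make_learner(learner_y, task, random_state=seed)
        model.fit(np.column_stack([X, z]), y)
        f1 = predict_values(model, np.column_stack([X, np.ones(len(y))]))
        f0 = predict_values(model, np.column_stack([X, np.zeros(len(y))]))
        return IATEEstimate(f1 - f0, method)

    # arm-specific first-stage fits, shared by T and X
    fits = {}
    for arm in (0, 1):
        mask = z == arm
        if mask.sum() < 2:
            raise DegenerateDesignError(f"treatment arm {arm} has fewer than 2 units")
        model = make_learner(learner_y, task, random_state=seed)
        model.fit(X[mask], y[mask])
        fits[arm] = model
    f0 = predict_values(fits[0], X)
    f1 = predict_values(fits[1], X)

    if method == "tlearner":
        return IATEEstimate(f1 - f0, method, m0_hat=f0, m1_hat=f1)

    if method == "xlearner":
        if ps_hat is None:
            raise ValueError("the X-learner needs propensity scores for weighting")
        ps = np.asarray(ps_hat, dtype=float)
        treated, control = z == 1, z == 0
        d1 = y[treated] - f0[treated]  # imputed effects among treated
        d0 = f1[control] - y[control]  # imputed effects among controls
        tau1_model = make_learner(learner_y, "regression", random_state=seed)
        tau1_model.fit(X[treated], d1)
        tau0_model = make_learner(learner_y, "regression", random_state=seed)
        tau0_model.fit(X[control], d0)
        tau1 = predict_values(tau1_model, X)
        tau0 = predict_values(tau0_model, X)
        # weight tau0 (fit on controls) by e(x), tau1 by 1 - e(x)
        return IATEEstimate(ps * tau0 + (1 - ps) * tau1, method,
                            ps_hat=ps, m0_hat=f0, m1_hat=f1)

    raise ValueError(f"unknown meta-learner {method!r}; known: {IATE_METHODS}")


def estimate_iate(
    X: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    method: str = "aipw",
    learner_ps: Any = "logistic",
    learner_y: Any = "linear",
    clip_eps: float = 0.01,
    n_folds: int = 2,
    seed: Optional[int] = None,
) -> IATEEstimate:
    """Dispatch to the requested IATE estimator."""
    if method == "aipw":
        ps = estimate_propensity(X, z, learner_ps, clip_eps, n_folds, seed)
        m0, m1 = fit_outcome_models(X, y, z, learner_y, n_folds, seed)
        tau = pseudo_outcome_aipw(y, z, ps, m0, m1)
        return IATEEstimate(tau, "aipw", ps_hat=ps, m0_hat=m0, m1_hat=m1)
    if method in ("slearner", "tlearner"):
        return meta_learner_iate(X, y, z, method, learner_y, seed=seed)
    if method == "xlearner":
        ps = estimate_propensity(X, z, learner_ps, clip_eps, n_folds, seed)
        return meta_learner_iate(X, y, z, method, learner_y, ps_hat=ps, seed=seed)
    raise ValueError(f"unknown IATE method {method!r}; known: {IATE_METHODS}")
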
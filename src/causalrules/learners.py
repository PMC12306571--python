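"""Registry of base learners behind a uniform fit/predict contract.

Learners are named by config strings ("linear", "logistic", "gbm", "rf",
"constant"); arbitrary user learners are accepted as scikit-learn style
estimators (``fit(X, y)`` / ``predict(X)``, plus ``predict_proba`` for
classification).  Classification learners always expose the probability of
the positive class through :func:`predict_values`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from sklearn.base import clone
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression


@dataclass
class BaseLearnerSpec:
    """A named learner plus free-form keyword settings."""

    name: str
    settings: dict[str, Any] = field(default_factory=dict)


_REGRESSORS = {
    "linear": LinearRegression,
    "gbm": GradientBoostingRegressor,
    "rf": RandomForestRegressor,
    "constant": lambda **kw: DummyRegressor(strategy="mean"),
}
_CLASSIFIERS = {
    "logistic": lambda **kw: LogisticRegression(max_iter=1000, **kw),
    "gbm": GradientBoostingClassifier,
    "rf": RandomForestClassifier,
    "constant": lambda **kw: DummyClassifier(strategy="prior"),
}
# names that resolve in either task (the task decides the variant)
KNOWN_LEARNERS = sorted(set(_REGRESSORS) | set(_CLASSIFIERS))


def resolve_spec(spec: Any) -> BaseLearnerSpec | Any:
    """Accept a name, a (name, settings) spec, or an estimator instance."""
    if isinstance(spec, str):
        return BaseLearnerSpec(spec)
    return spec


def make_learner(spec: Any, task: str, random_state: Optional[int] = None) -> Any:
    """Instantiate a learner for ``task`` in {"regression", "classification"}."""
    spec = resolve_spec(spec)
    if not isinstance(spec, BaseLearnerSpec):
        return clone(spec)  # user-supplied estimator template
    table = _REGRESSORS if task == "regression" else _CLASSIFIERS
    if spec.name not in table:
        raise ValueError(
            f"unknown {task} learner {spec.name!r}; known: {KNOWN_LEARNERS}"
        )
    factory = table[spec.name]
    kwargs = dict(spec.settings)
    est = factory(**kwargs)
    if random_state is not None and "random_state" in est.get_params():
        est.set_params(random_state=random_state)
    return est


def predict_values(model: Any, X: np.ndarray) -> np.ndarray:
    """Numeric predictions: probabilities of class 1 for classifiers."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        classes = np.asarray(model.classes_)
        if proba.shape[1] == 1:  # single class seen in training
            return np.full(X.shape[0], float(classes[0]))
        return proba[:, int(np.argmax(classes))]
    return np.asarray(model.predict(X), dtype=float)
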
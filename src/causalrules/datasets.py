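"""Synthetic observational datasets with a known sparse rule decomposition.

The generator produces ``(y, z, X)`` triplets whose conditional average
treatment effect is *exactly* a sum of ``n_rules`` decision-rule
contributions of magnitude ``effect_size``, so every downstream stage of
the pipeline can be checked against a ground truth.

The fixed rule template (with ``xj = 1`` meaning ``xj > 0.5`` for
continuous covariates):

====  =======================  ======
rule  condition                AATE
====  =======================  ======
1     x1=1 and x2=1            +effect_size
2     x5=1 and x6=1            -effect_size
3     x4=1                     +effect_size
4     x5=1 and x7=1 and x8=1   -effect_size
====  =======================  ======

The first ``n_rules`` rows are used.  Covariates share an exchangeable
latent Gaussian correlation ``rho`` (a Gaussian copula): binary covariates
threshold the latent normal at 0, continuous covariates map it through the
standard normal CDF onto [0, 1].  Treatment is Bernoulli with propensity
0.5 ("no" confounding), logistic-linear in (x1, x2) ("lin"), or logistic
with an interaction term ("nonlin").  The continuous outcome is
``y = b(X) + z * ite + eps`` with linear baseline ``b(X) = x1 + x2 + x3``
and standard normal noise; binary outcomes threshold the latent continuous
outcome at its median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .rules import Condition, DecisionRule

CONFOUNDING_MODES = ("no", "lin", "nonlin")

# (covariate indices, sign) per template rule, 0-based.
_TEMPLATE = (
    ((0, 1), +1.0),
    ((4, 5), -1.0),
    ((3,), +1.0),
    ((4, 6, 7), -1.0),
)


@dataclass
class GeneratorParams:
    """Parameters of the synthetic data-generating process."""

    n: int = 5000
    p: int = 10
    rho: float = 0.0
    n_rules: int = 2
    effect_size: float = 2.0
    binary_covariates: bool = True
    binary_outcome: bool = False
    confounding: str = "no"
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValueError("n must be a positive integer")
        if not (isinstance(self.p, (int, np.integer)) and self.p > 0):
            raise ValueError("p must be a positive integer")
        if not (np.isfinite(self.rho) and 0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.n_rules not in (1, 2, 3, 4):
            raise ValueError("n_rules must be one of {1, 2, 3, 4}")
        if not (np.isfinite(self.effect_size) and self.effect_size >= 0):
            raise ValueError("effect_size must be a finite non-negative real")
        if self.confounding not in CONFOUNDING_MODES:
            raise ValueError(f"confounding must be one of {CONFOUNDING_MODES}")
        p_needed = max(max(vars_) for vars_, _ in _TEMPLATE[: self.n_rules]) + 1
        if self.p < p_needed:
            raise ValueError(
                f"p={self.p} too small for the {self.n_rules}-rule template "
                f"(needs p >= {p_needed})"
            )
        if self.confounding != "no" and self.p < 3:
            raise ValueError("confounded designs need p >= 3")


@dataclass
class SyntheticDataset:
    """A generated dataset together with its ground truth."""

    y: np.ndarray
    z: np.ndarray
    X: np.ndarray
    ite: np.ndarray
    true_rules: list[DecisionRule]
    true_aates: np.ndarray
    params: GeneratorParams = field(repr=False)

    @property
    def ate_true(self) -> float:
        return float(self.ite.mean())


def true_decomposition(
    params: GeneratorParams,
) -> tuple[list[DecisionRule], np.ndarray]:
    """The canonical rule template and its AATEs; deterministic."""
    params.validate()
    rules, aates = [], []
    for vars_, sign in _TEMPLATE[: params.n_rules]:
        conds = tuple(Condition(v, "gt", 0.5) for v in vars_)
        rules.append(DecisionRule(conds))
        aates.append(sign * params.effect_size)
    return rules, np.asarray(aates, dtype=float)


def _correlated_latents(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """Latent normals with exchangeable correlation rho (one-factor form)."""
    g = rng.standard_normal((n, p))
    if rho == 0:
        return g
    common = rng.standard_normal((n, 1))
    return np.sqrt(rho) * common + np.sqrt(1 - rho) * g


def _expit(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def generate_dataset(params: GeneratorParams) -> SyntheticDataset:
    """Draw one dataset; identical ``params`` (incl. seed) give identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    latent = _correlated_latents(rng, params.n, params.p, params.rho)
    if params.binary_covariates:
        X = (latent > 0).astype(float)
    else:
        X = norm.cdf(latent)

    rules, aates = true_decomposition(params)
    R = np.column_stack([r.evaluate(X) for r in rules])
    ite = R @ aates

    if params.confounding == "no":
        ps = np.full(params.n, 0.5)
    elif params.confounding == "lin":
        ps = _expit(-1.0 + X[:, 0] + X[:, 1])
    else:  # nonlin
        ps = _expit(-1.0 + X[:, 0] * X[:, 1] + X[:, 2])
    z = (rng.uniform(size=params.n) < ps).astype(float)

    baseline = X[:, 0] + X[:, 1] + X[:, 2] if params.p >= 3 else X[:, :1].sum(axis=1)
    y_latent = baseline + z * ite + rng.standard_normal(params.n)
    if params.binary_outcome:
        y = (y_latent > np.median(y_latent)).astype(float)
    else:
        y = y_latent

    return SyntheticDataset(
        y=y, z=z, X=X, ite=ite, true_rules=rules, true_aates=aates, params=params
    )
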
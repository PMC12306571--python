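"""Decision rules: conjunctions of threshold conditions on covariates.

A decision rule ``r(x)`` is a conjunction of atomic conditions of the form
``x_j <= t`` or ``x_j > t``.  Evaluated on a covariate matrix it yields a
0/1 indicator of membership in the subgroup it describes.  Rules are stored
in a canonical form so that logically identical conjunctions compare equal:
per variable at most one upper bound (``<=``) and one lower bound (``>``)
survive, and conditions are sorted by variable index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class Condition:
    """A single threshold condition ``x[var] op threshold``.

    ``op`` is ``"le"`` (non-strict upper bound) or ``"gt"`` (strict lower
    bound), matching the left/right branches of a binary decision tree.
    """

    var: int
    op: str  # "le" | "gt"
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("le", "gt"):
            raise ValueError(f"unknown condition operator {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("condition threshold must be finite")
        if self.var < 0:
            raise ValueError("variable index must be non-negative")

    def holds(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.var]
        return col <= self.threshold if self.op == "le" else col > self.threshold

    def text(self, names: Optional[Sequence[str]] = None) -> str:
        name = names[self.var] if names is not None else f"x{self.var + 1}"
        sym = "<=" if self.op == "le" else ">"
        return f"{name}{sym}{_fmt(self.threshold)}"


def _fmt(t: float) -> str:
    return f"{t:g}"


class ContradictoryRuleError(ValueError):
    """The conjunction describes an empty region of covariate space."""


@dataclass(frozen=True)
class DecisionRule:
    """A canonical conjunction of :class:`Condition` atoms.

    Construction canonicalizes the condition list: per variable the bounds
    are intersected (max of lower bounds, min of upper bounds), conditions
    are sorted by variable index (``le`` before ``gt``), and a conjunction
    whose region is empty raises :class:`ContradictoryRuleError`.
    """

    conditions: tuple[Condition, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a decision rule needs at least one condition")
        object.__setattr__(self, "conditions", canonical_conditions(self.conditions))

    @property
    def depth(self) -> int:
        return len(self.conditions)

    @property
    def canonical_key(self) -> str:
        return self.text()

    def text(self, names: Optional[Sequence[str]] = None) -> str:
        return " & ".join(c.text(names) for c in self.conditions)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """0/1 indicator of the rule holding, one entry per row of ``X``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        vmax = max(c.var for c in self.conditions)
        if vmax >= X.shape[1]:
            raise KeyError(
                f"rule refers to covariate index {vmax} but X has {X.shape[1]} columns"
            )
        out = np.ones(X.shape[0], dtype=bool)
        for c in self.conditions:
            out &= c.holds(X)
        return out.astype(float)

    def drop_last(self) -> "DecisionRule":
        if self.depth == 1:
            return self
        return DecisionRule(self.conditions[:-1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text()


def canonical_conditions(conditions: Iterable[Condition]) -> tuple[Condition, ...]:
    """Intersect per-variable intervals and sort; reject empty regions."""
    lower: dict[int, float] = {}
    upper: dict[int, float] = {}
    for c in conditions:
        if c.op == "gt":
            lower[c.var] = max(lower.get(c.var, -np.inf), c.threshold)
        else:
            upper[c.var] = min(upper.get(c.var, np.inf), c.threshold)
    out: list[Condition] = []
    for var in sorted(set(lower) | set(upper)):
        lo, up = lower.get(var), upper.get(var)
        if lo is not None and up is not None and lo >= up:
            raise ContradictoryRuleError(
                f"empty region for variable {var}: >{lo} and <={up}"
            )
        if up is not None:
            out.append(Condition(var, "le", up))
        if lo is not None:
            out.append(Condition(var, "gt", lo))
    return tuple(out)


def rule_from_text(text: str) -> DecisionRule:
    """Parse a rule from its canonical text form, e.g. ``"x1>0.5 & x3<=2"``."""
    conds = []
    for atom in text.split("&"):
        atom = atom.strip()
        if "<=" in atom:
            name, t = atom.split("<=")
            op = "le"
        elif ">" in atom:
            name, t = atom.split(">")
            op = "gt"
        else:
            raise ValueError(f"cannot parse condition {atom!r}")
        name = name.strip()
        if not name.startswith("x"):
            raise ValueError(f"cannot parse variable name {name!r}")
        conds.append(Condition(int(name[1:]) - 1, op, float(t)))
    return DecisionRule(tuple(conds))


@dataclass
class RuleMatrix:
    """n x M binary indicator matrix with its aligned rule list."""

    indicators: np.ndarray
    rules: list[DecisionRule]

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=float)
        if self.indicators.ndim != 2:
            raise ValueError("indicator matrix must be 2-d")
        if self.indicators.shape[1] != len(self.rules):
            raise ValueError("indicator columns must align with rules")

    @property
    def n(self) -> int:
        return self.indicators.shape[0]

    @property
    def M(self) -> int:
        return self.indicators.shape[1]


def build_rule_matrix(rules: Sequence[DecisionRule], X: np.ndarray) -> RuleMatrix:
    """Evaluate each rule on ``X``; constant columns are a consistency error."""
    X = np.asarray(X, dtype=float)
    if len(rules) == 0:
        return RuleMatrix(np.empty((X.shape[0], 0)), [])
    cols = np.column_stack([r.evaluate(X) for r in rules])
    means = cols.mean(axis=0)
    if np.any((means == 0) | (means == 1)):
        bad = [rules[i].canonical_key for i in np.flatnonzero((means == 0) | (means == 1))]
        raise ValueError(f"constant rule columns (should have been filtered): {bad}")
    return RuleMatrix(cols, list(rules))
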
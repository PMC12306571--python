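"""Pipeline configuration: method parameters, hyper parameters, seeding."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Optional

import numpy as np

from .iate import IATE_METHODS
from .selection import SELECTION_MODES

# fixed stage codes so per-stage RNG streams are stable across versions
_STAGE_CODES = {
    "split": 0,
    "iate_discovery": 1,
    "iate_inference": 2,
    "trees": 3,
    "stability": 4,
    "bootstrap": 5,
    "simulate": 6,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2^31) from the top-level seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_CODES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Resolved configuration of the full pipeline.

    Method parameters control IATE estimation and the honest split; hyper
    parameters control rule generation, filtering, stability selection and
    bootstrap inference.  Defaults follow the method's standard settings.
    """

    # method parameters
    ratio_dis: float = 0.5
    ite_method: str = "aipw"
    learner_ps: Any = "gbm"
    learner_y: Any = "gbm"
    clip_eps: float = 0.01
    n_folds: int = 2
    # hyper parameters
    intervention_vars: Optional[list[int]] = None
    offset: Optional[str] = None  # accepted and echoed; not consumed (v1)
    ntrees: int = 20
    node_size: int = 20
    max_rules: int = 100
    max_depth: int = 3
    t_decay: float = 0.025
    t_ext: float = 0.025
    t_corr: float = 1.0
    t_pvalue: float = 0.05
    stability_selection: str = "vanilla"
    cutoff: float = 0.9
    pfer: float = 0.1
    B: int = 50
    subsample: float = 0.05
    alpha: float = 0.05
    n_boot: int = 200
    # seeding
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.ratio_dis < 1):
            raise ValueError("ratio_dis must lie in (0, 1)")
        if self.ite_method not in IATE_METHODS:
            raise ValueError(
                f"ite_method must be one of {IATE_METHODS}, got {self.ite_method!r}"
            )
        if not (0 < self.clip_eps < 0.5):
            raise ValueError("clip_eps must lie in (0, 0.5)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.stability_selection not in SELECTION_MODES:
            raise ValueError(
                f"stability_selection must be one of {SELECTION_MODES}"
            )
        if min(self.ntrees, self.node_size, self.max_depth, self.max_rules) < 1:
            raise ValueError("tree/rule count parameters must be >= 1")
        if not (0 <= self.t_ext < 0.5):
            raise ValueError("t_ext must lie in [0, 0.5)")
        if not (0 < self.t_corr <= 1):
            raise ValueError("t_corr must lie in (0, 1]")
        if not (0 < self.t_pvalue <= 1):
            raise ValueError("t_pvalue must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.t_decay < 0:
            raise ValueError("t_decay must be non-negative")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v if not isinstance(v, np.ndarray) else v.tolist()
        return out

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
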
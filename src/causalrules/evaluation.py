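"""Simulation-study helpers: coverage and recovery rates on synthetic data."""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .datasets import GeneratorParams, generate_dataset
from .iate import estimate_propensity, fit_outcome_models, pseudo_outcome_aipw
from .inference import forced_rule_inference, honest_split
from .pipeline import cre_fit


def aate_ci_coverage(
    params: GeneratorParams,
    n_datasets: int = 100,
    seed: int = 1,
    ratio_dis: float = 0.5,
    learner_ps: str = "gbm",
    learner_y: str = "gbm",
    n_boot: int = 200,
    alpha: float = 0.05,
) -> float:
    """Empirical coverage of bootstrap percentile CIs for the AATEs.

    For each replicate: draw a dataset, compute AIPW pseudo-outcomes on the
    honest inference half, force the true rule template as the selected
    set, fit the decomposition with bootstrap intervals, and record whether
    each true AATE lies inside its interval.  Returns the covered fraction
    over all (dataset, rule) pairs.
    """
    base = int(seed) % (2**20)
    covered = total = 0
    for i in range(1, n_datasets + 1):
        ds = generate_dataset(replace(params, seed=base * 1000 + i))
        _, inf = honest_split(params.n, ratio_dis, seed=base * 1000 + 500 + i)
        X, y, z = ds.X[inf], ds.y[inf], ds.z[inf]
        ps = estimate_propensity(X, z, learner_ps, seed=base + 2 * i)
        m0, m1 = fit_outcome_models(X, y, z, learner_y, seed=base + 2 * i + 1)
        tau = pseudo_outcome_aipw(y, z, ps, m0, m1)
        model = forced_rule_inference(
            ds.true_rules, X, tau, n_boot=n_boot, alpha=alpha, seed=base + 7 * i
        )
        covered += int(
            np.sum((model.ci_low <= ds.true_aates) & (ds.true_aates <= model.ci_high))
        )
        total += len(ds.true_aates)
    return covered / total


def rule_recovery_rate(
    params: GeneratorParams,
    n_datasets: int = 20,
    seed: int = 1,
    config: Optional[PipelineConfig] = None,
) -> float:
    """Fraction of replicates whose final rule set equals the true template."""
    base = int(seed) % (2**20)
    hits = 0
    for i in range(1, n_datasets + 1):
        ds = generate_dataset(replace(params, seed=base * 1000 + i))
        cfg = config if config is not None else PipelineConfig()
        cfg = replace(cfg, seed=base * 1000 + i)
        res = cre_fit(ds.y, ds.z, ds.X, config=cfg)
        truth = {r.canonical_key for r in ds.true_rules}
        got = {r.canonical_key for r in res.decomposition.rules}
        hits += got == truth
    return hits / n_datasets
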
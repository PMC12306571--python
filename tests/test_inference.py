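"""Honest splitting, OLS decomposition, bootstrap CIs, p-value pruning."""

import itertools
import warnings

import numpy as np
import pytest

from causalrules import (
    bootstrap_inference,
    fit_decomposition,
    forced_rule_inference,
    honest_split,
    predict_cate,
    prune_by_pvalue,
)
from causalrules.inference import (
    CATEDecomposition,
    DegenerateDesignError,
    drop_collinear,
    fit_and_infer,
)
from causalrules.rules import Condition, DecisionRule, RuleMatrix, build_rule_matrix


def _rule(var):
    return DecisionRule((Condition(var, "gt", 0.5),))


def test_honest_split_sizes_disjoint_exhaustive():
    dis, inf = honest_split(5000, 0.5, seed=0)
    assert len(dis) == 2500 and len(inf) == 2500
    assert len(np.intersect1d(dis, inf)) == 0
    np.testing.assert_array_equal(np.sort(np.r_[dis, inf]), np.arange(5000))


def test_honest_split_determinism_and_boundaries():
    a = honest_split(100, 0.3, seed=7)
    b = honest_split(100, 0.3, seed=7)
    np.testing.assert_array_equal(a[0], b[0])
    with pytest.raises(ValueError):
        honest_split(10, 0.999)  # inference side empty after ceiling
    with pytest.raises(ValueError):
        honest_split(10, 0.0)


def test_intercept_only_fit_is_mean():
    tau = np.array([1.0, 2.0, 6.0])
    ate, aate = fit_decomposition(np.empty((3, 0)), tau)
    assert ate == pytest.approx(3.0)
    assert aate.size == 0


def test_exact_linear_data_recovered():
    rng = np.random.default_rng(0)
    r = (rng.uniform(size=200) > 0.5).astype(float)
    tau = 2.0 + 3.0 * r
    ate, aate = fit_decomposition(r[:, None], tau)
    assert ate == pytest.approx(2.0, abs=1e-10)
    assert aate[0] == pytest.approx(3.0, abs=1e-10)


def test_ols_matches_explicit_normal_equations():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n, m = rng.integers(20, 60), rng.integers(1, 5)
        R = (rng.uniform(size=(n, m)) > 0.5).astype(float)
        tau = rng.standard_normal(n)
        D = np.column_stack([np.ones(n), R])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            continue
        beta = np.linalg.solve(D.T @ D, D.T @ tau)
        ate, aate = fit_decomposition(R, tau)
        np.testing.assert_allclose(np.r_[ate, aate], beta, rtol=1e-8)


def test_rank_deficiency_raises_and_drop_collinear_recovers():
    rng = np.random.default_rng(1)
    col = (rng.uniform(size=100) > 0.5).astype(float)
    R = np.column_stack([col, col])
    with pytest.raises(DegenerateDesignError):
        fit_decomposition(R, rng.standard_normal(100))
    rm = RuleMatrix(R, [_rule(0), _rule(1)])
    with pytest.warns(UserWarning, match="collinear"):
        reduced, kept = drop_collinear(rm)
    assert kept == [0] and reduced.M == 1


def test_bootstrap_degenerate_on_exact_data():
    rng = np.random.default_rng(2)
    r = (rng.uniform(size=300) > 0.5).astype(float)
    tau = 1.0 + 4.0 * r  # noiseless
    lo, hi, pv, _ = bootstrap_inference(r[:, None], tau, n_boot=100, seed=0)
    np.testing.assert_allclose(hi - lo, 0.0, atol=1e-10)
    np.testing.assert_array_equal(pv, [0.0, 0.0])


def test_bootstrap_parameter_guards():
    r = np.r_[np.zeros(5), np.ones(5)][:, None]
    tau = np.arange(10.0)
    with pytest.raises(ValueError):
        bootstrap_inference(r, tau, n_boot=1)
    with pytest.raises(ValueError):
        bootstrap_inference(r, tau, alpha=1.5)


def test_bootstrap_ci_brackets_point_estimate(rng):
    r = (rng.uniform(size=500) > 0.5).astype(float)
    tau = 2.0 + 3.0 * r + rng.standard_normal(500)
    ate, aate = fit_decomposition(r[:, None], tau)
    lo, hi, pv, boot = bootstrap_inference(r[:, None], tau, n_boot=200, seed=1)
    assert lo[1] <= aate[0] <= hi[1]
    assert boot.shape == (200, 2)
    assert pv[1] < 0.001  # strong true effect


def test_prune_tpvalue_one_is_noop(rng):
    r = (rng.uniform(size=400) > 0.5).astype(float)
    tau = 1.0 + 2.0 * r + rng.standard_normal(400)
    R = RuleMatrix(r[:, None], [_rule(0)])
    model = fit_and_infer(R, tau, n_boot=100, seed=3)
    pruned = prune_by_pvalue(model, 1.0, R, tau, n_boot=100, seed=3)
    assert pruned.M_final == 1
    np.testing.assert_array_equal(pruned.aate, model.aate)


def test_null_rules_usually_pruned_to_ate_only():
    dropped = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        col = (r.uniform(size=2000) > 0.5).astype(float)
        tau = r.standard_normal(2000)  # rule explains nothing
        R = RuleMatrix(col[:, None], [_rule(0)])
        model = fit_and_infer(R, tau, n_boot=100, seed=seed)
        pruned = prune_by_pvalue(model, 0.05, R, tau, n_boot=100, seed=seed)
        dropped += pruned.M_final == 0
        if pruned.M_final == 0:
            assert pruned.ate == pytest.approx(tau.mean(), abs=1e-8)
    assert dropped >= 7


def test_prune_invalid_threshold(rng):
    r = (rng.uniform(size=100) > 0.5).astype(float)
    tau = r + rng.standard_normal(100)
    R = RuleMatrix(r[:, None], [_rule(0)])
    model = fit_and_infer(R, tau, n_boot=50, seed=0)
    with pytest.raises(ValueError):
        prune_by_pvalue(model, 0.0, R, tau)


def _manual_model(ate, rules, aate):
    k = len(rules)
    return CATEDecomposition(
        ate=ate, rules=rules, aate=np.asarray(aate, dtype=float),
        ci_low=np.zeros(k), ci_high=np.zeros(k), pvalues=np.zeros(k),
    )


def test_predict_constant_without_rules():
    model = _manual_model(1.5, [], [])
    np.testing.assert_array_equal(
        predict_cate(model, np.zeros((4, 3))), np.full(4, 1.5)
    )


def test_predict_enumerates_decomposition_table():
    """At p = 3 binary covariates the prediction matches the hand-computed
    decomposition on every pattern."""
    r1 = DecisionRule((Condition(0, "gt", 0.5), Condition(1, "gt", 0.5)))
    r2 = DecisionRule((Condition(2, "gt", 0.5),))
    model = _manual_model(0.5, [r1, r2], [2.0, -1.0])
    X = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
    expect = 0.5 + 2.0 * (X[:, 0] * X[:, 1]) - 1.0 * X[:, 2]
    np.testing.assert_allclose(model.predict(X), expect)
    # a row satisfying no rule gets exactly the ATE
    assert model.predict(np.zeros((1, 3)))[0] == pytest.approx(0.5)


def test_predict_schema_error():
    model = _manual_model(0.0, [_rule(4)], [1.0])
    with pytest.raises(KeyError):
        predict_cate(model, np.zeros((2, 3)))


def test_forced_rule_inference_recovers_known_aates(two_rule_dataset):
    ds = two_rule_dataset
    tau = ds.ite + np.random.default_rng(0).standard_normal(len(ds.ite))
    model = forced_rule_inference(ds.true_rules, ds.X, tau, n_boot=100, seed=1)
    np.testing.assert_allclose(model.aate, ds.true_aates, atol=0.5)
    assert np.all(model.ci_low <= model.aate) and np.all(model.aate <= model.ci_high)


def test_honesty_discovery_rows_never_reach_inference(monkeypatch):
    """The two IATE estimations see disjoint, exhaustive row sets."""
    import causalrules.pipeline as pl
    from causalrules import PipelineConfig, cre_fit
    from causalrules.iate import IATEEstimate

    n = 200
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(n, 4))
    X[:, 0] = np.arange(n) / n  # unique row ids
    y = rng.standard_normal(n)
    z = (rng.uniform(size=n) > 0.5).astype(float)

    seen = []

    def spy(Xs, ys, zs, **kw):
        seen.append(set(np.round(Xs[:, 0] * n).astype(int)))
        return IATEEstimate(np.asarray(ys) * 0 + rng.standard_normal(len(ys)), "aipw")

    monkeypatch.setattr(pl, "estimate_iate", spy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cre_fit(y, z, X, config=PipelineConfig(seed=1, subsample=0.2))
    assert len(seen) == 2
    assert seen[0] & seen[1] == set()
    assert seen[0] | seen[1] == set(range(n))


def test_build_rule_matrix_then_fit_shapes(four_rule_dataset):
    ds = four_rule_dataset
    R = build_rule_matrix(ds.true_rules, ds.X)
    assert R.indicators.shape == (len(ds.y), 4)
    ate, aate = fit_decomposition(R, ds.ite)
    np.testing.assert_allclose(aate, ds.true_aates, atol=1e-8)
    assert ate == pytest.approx(0.0, abs=1e-8)
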
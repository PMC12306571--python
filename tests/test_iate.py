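"""IATE estimators: AIPW pseudo-outcomes and the S/T/X meta-learners."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

from causalrules import (
    GeneratorParams,
    estimate_iate,
    estimate_propensity,
    generate_dataset,
    meta_learner_iate,
    pseudo_outcome_aipw,
)
from causalrules.iate import DegenerateDesignError, fit_outcome_models


def test_aipw_formula_point_cases():
    tau = pseudo_outcome_aipw(
        y=np.array([1.0]), z=np.array([1.0]), ps_hat=np.array([0.5]),
        m0_hat=np.array([0.0]), m1_hat=np.array([0.0]),
    )
    assert tau[0] == pytest.approx(2.0)
    tau = pseudo_outcome_aipw(
        y=np.array([1.0]), z=np.array([0.0]), ps_hat=np.array([0.25]),
        m0_hat=np.array([0.0]), m1_hat=np.array([3.0]),
    )
    # m1 - m0 - (y - m0)/(1 - e) = 3 - 1/0.75
    assert tau[0] == pytest.approx(3.0 - 1 / 0.75)


def test_aipw_exact_outcome_models_recover_ite_pointwise(two_rule_dataset):
    """When m1 - m0 = ite and residuals vanish, tau_hat = ite exactly."""
    ds = two_rule_dataset
    m1 = np.where(ds.z == 1, ds.y, ds.y + ds.ite)
    m0 = np.where(ds.z == 0, ds.y, ds.y - ds.ite)
    tau = pseudo_outcome_aipw(ds.y, ds.z, np.full(len(ds.y), 0.5), m0, m1)
    np.testing.assert_allclose(tau, ds.ite, atol=1e-10)


def test_aipw_unclipped_propensity_rejected():
    with pytest.raises(ValueError):
        pseudo_outcome_aipw(
            np.ones(2), np.array([0.0, 1.0]), np.array([0.0, 1.0]),
            np.zeros(2), np.zeros(2),
        )


def test_aipw_double_robustness_monte_carlo():
    """Wrong outcome models with true ps, and wrong ps with true outcome
    models, both recover mean(ite) at large n."""
    ds = generate_dataset(GeneratorParams(n=100000, n_rules=2, effect_size=3.0, seed=21))
    n = len(ds.y)
    se = 3 * ds.y.std() / np.sqrt(n) * 4  # loose Monte-Carlo band
    # correct ps, useless outcome models
    tau = pseudo_outcome_aipw(ds.y, ds.z, np.full(n, 0.5), np.zeros(n), np.zeros(n))
    assert abs(tau.mean() - ds.ite.mean()) < se
    # wrong ps, correct outcome models
    m0 = ds.X[:, 0] + ds.X[:, 1] + ds.X[:, 2]
    m1 = m0 + ds.ite
    tau = pseudo_outcome_aipw(ds.y, ds.z, np.full(n, 0.3), m0, m1)
    assert abs(tau.mean() - ds.ite.mean()) < se


def test_propensity_constant_learner_is_treated_share(two_rule_dataset):
    ds = two_rule_dataset
    ps = estimate_propensity(ds.X, ds.z, "constant", seed=0)
    # cross-fitted: each fold predicts the other's treated share
    assert np.all(np.abs(ps - ds.z.mean()) < 0.05)


def test_propensity_unconfounded_near_half(two_rule_dataset):
    ds = two_rule_dataset
    ps = estimate_propensity(ds.X, ds.z, "logistic", seed=0)
    assert abs(ps.mean() - 0.5) < 0.05
    assert ps.min() >= 0.01 and ps.max() <= 0.99


def test_propensity_recovers_linear_confounding():
    ds = generate_dataset(GeneratorParams(n=5000, seed=17, confounding="lin"))
    ps = estimate_propensity(ds.X, ds.z, "logistic", seed=0)
    truth = 1 / (1 + np.exp(1 - ds.X[:, 0] - ds.X[:, 1]))
    assert np.mean(np.abs(ps - truth)) < 0.1


def test_propensity_degenerate_design():
    X = np.random.default_rng(0).uniform(size=(40, 3))
    with pytest.raises(DegenerateDesignError):
        estimate_propensity(X, np.ones(40), "logistic")
    with pytest.raises(ValueError):
        estimate_propensity(X, np.zeros(40) + 2, "logistic")


def test_propensity_clip_eps_bounds_enforced():
    X = np.random.default_rng(0).uniform(size=(40, 3))
    z = np.r_[np.zeros(20), np.ones(20)]
    with pytest.raises(ValueError):
        estimate_propensity(X, z, "logistic", clip_eps=0.6)


@pytest.mark.parametrize("method", ["tlearner", "xlearner"])
def test_constant_learner_reduces_to_difference_in_means(method, two_rule_dataset):
    """Arm-wise intercept-only fits collapse the T- and X-learner to the
    plain difference in means."""
    ds = two_rule_dataset
    diff = ds.y[ds.z == 1].mean() - ds.y[ds.z == 0].mean()
    est = meta_learner_iate(
        ds.X, ds.y, ds.z, method, learner_y="constant",
        ps_hat=np.full(len(ds.y), 0.5),
    )
    np.testing.assert_allclose(est.tau_hat, diff, atol=1e-10)


def test_constant_learner_slearner_sees_no_effect(two_rule_dataset):
    """A single intercept-only model ignores the treatment column, so the
    S-learner contrast f(x,1) - f(x,0) is identically zero."""
    ds = two_rule_dataset
    est = meta_learner_iate(ds.X, ds.y, ds.z, "slearner", learner_y="constant")
    np.testing.assert_allclose(est.tau_hat, 0.0, atol=1e-12)


def test_tlearner_saturated_matches_cellwise_difference_of_means():
    """With a saturated learner on 2 binary covariates the T-learner equals
    the stratified brute-force estimate in every cell."""
    rng = np.random.default_rng(7)
    n = 4000
    X = (rng.uniform(size=(n, 2)) > 0.5).astype(float)
    z = (rng.uniform(size=n) > 0.5).astype(float)
    y = X[:, 0] + z * (2 * X[:, 1] - 1) + rng.standard_normal(n)
    est = meta_learner_iate(
        X, y, z, "tlearner",
        learner_y=DecisionTreeRegressor(max_depth=2, random_state=0),
    )
    for a in (0.0, 1.0):
        for b in (0.0, 1.0):
            cell = (X[:, 0] == a) & (X[:, 1] == b)
            brute = y[cell & (z == 1)].mean() - y[cell & (z == 0)].mean()
            np.testing.assert_allclose(est.tau_hat[cell], brute, atol=1e-10)


def test_xlearner_equal_weights_averages_the_two_stages():
    rng = np.random.default_rng(3)
    n = 500
    X = rng.uniform(size=(n, 3))
    z = (rng.uniform(size=n) > 0.5).astype(float)
    y = X @ [1.0, -1.0, 0.5] + z * X[:, 0] + rng.standard_normal(n)
    ps = np.full(n, 0.5)
    est = meta_learner_iate(X, y, z, "xlearner", learner_y="linear", ps_hat=ps)

    # manual two-stage construction with the same linear learner
    f0 = LinearRegression().fit(X[z == 0], y[z == 0]).predict(X)
    f1 = LinearRegression().fit(X[z == 1], y[z == 1]).predict(X)
    tau1 = LinearRegression().fit(X[z == 1], y[z == 1] - f0[z == 1]).predict(X)
    tau0 = LinearRegression().fit(X[z == 0], f1[z == 0] - y[z == 0]).predict(X)
    np.testing.assert_allclose(est.tau_hat, 0.5 * tau0 + 0.5 * tau1, atol=1e-8)


def test_xlearner_requires_propensity():
    X = np.random.default_rng(0).uniform(size=(40, 2))
    z = np.r_[np.zeros(20), np.ones(20)]
    with pytest.raises(ValueError):
        meta_learner_iate(X, np.ones(40), z, "xlearner")


def test_outcome_models_binary_outcome_uses_probabilities():
    ds = generate_dataset(GeneratorParams(n=800, binary_outcome=True, seed=19))
    m0, m1 = fit_outcome_models(ds.X, ds.y, ds.z, "logistic", seed=0)
    assert np.all((m0 >= 0) & (m0 <= 1)) and np.all((m1 >= 0) & (m1 <= 1))


def test_estimate_iate_aipw_unbiased_monte_carlo():
    ds = generate_dataset(GeneratorParams(n=30000, n_rules=2, effect_size=3.0, seed=23))
    est = estimate_iate(ds.X, ds.y, ds.z, method="aipw",
                        learner_ps="logistic", learner_y="linear", seed=1)
    se = est.tau_hat.std() / np.sqrt(len(ds.y))
    assert abs(est.tau_hat.mean() - ds.ite.mean()) < 4 * se
    assert est.ps_hat is not None and est.m0_hat is not None


def test_unknown_method_and_learner_rejected(two_rule_dataset):
    ds = two_rule_dataset
    with pytest.raises(ValueError, match="unknown IATE method"):
        estimate_iate(ds.X, ds.y, ds.z, method="causal_forest")
    with pytest.raises(ValueError, match="unknown"):
        estimate_propensity(ds.X, ds.z, "svm")
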
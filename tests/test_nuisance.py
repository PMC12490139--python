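"""Learners and nuisance-function fitting."""

import numpy as np
import pandas as pd
import pytest

import cfrisk as cf
from cfrisk.exceptions import DomainError, EstimabilityError
from cfrisk.learners import make_learner
from cfrisk.nuisance import CrossFitRegression

from conftest import make_dataset


@pytest.fixture
def simple_ds():
    rows = [
        (0, 0.0, 1, 7.0), (0, 0.0, 1, 7.0), (0, 1.0, 0, 7.0), (0, 1.0, 1, 7.0),
        (1, 0.0, 1, 7.0), (1, 1.0, 0, 7.0), (1, 1.0, 1, 7.0), (1, 0.0, 0, 7.0),
    ]
    return make_dataset(rows)


@pytest.mark.parametrize("learner", ["linear", "intercept", "saturated"])
def test_constant_response_predicts_constant(simple_ds, learner):
    losses = np.full(simple_ds.n, 7.0)
    fit = cf.fit_loss_regression(simple_ds, losses, a=1, source=0, learner=learner)
    preds = fit.predict(simple_ds.x)
    assert np.allclose(preds, 7.0, atol=1e-10)


def test_saturated_learner_recovers_group_means():
    rows = [
        (0, 0.0, 1, 1.0), (0, 0.0, 1, np.sqrt(3)), (0, 1.0, 1, np.sqrt(5)),
        (1, 0.0, 1, 0.0),
    ]
    ds = make_dataset(rows)
    losses = ds.y**2  # {1, 3} at X=0, {5} at X=1 in the (S=0, A=1) cell
    fit = cf.fit_loss_regression(ds, losses, a=1, source=0, learner="saturated")
    assert fit.predict(pd.DataFrame({"x": [0.0, 1.0]})) == pytest.approx([2.0, 5.0])


def test_saturated_learner_rejects_unseen_pattern():
    model = make_learner("saturated").fit(np.array([[0.0], [1.0]]), [1.0, 2.0])
    with pytest.raises(EstimabilityError):
        model.predict(np.array([[2.0]]))


def test_empty_cell_is_estimability_error(simple_ds):
    ds = make_dataset([(0, 0.0, 0, 1.0), (0, 1.0, 0, 2.0),
                       (1, 0.0, 1, 1.0), (1, 1.0, 0, 2.0)])
    with pytest.raises(EstimabilityError):
        cf.fit_loss_regression(ds, np.ones(ds.n), a=1, source=0)


def test_nonfinite_losses_rejected(simple_ds):
    losses = np.full(simple_ds.n, 1.0)
    losses[0] = np.inf
    with pytest.raises(DomainError):
        cf.fit_loss_regression(simple_ds, losses, a=1, source=0)


def test_single_treatment_level_stratum_rejected():
    ds = make_dataset([(0, 0.0, 1, 1.0), (0, 1.0, 1, 2.0),
                       (1, 0.0, 1, 1.0), (1, 1.0, 0, 2.0)])
    with pytest.raises(EstimabilityError):
        cf.fit_treatment_model(ds, 0)


def test_intercept_propensity_matches_frequency(simple_ds):
    fit = cf.fit_treatment_model(simple_ds, 0, learner="intercept")
    assert fit.prob(simple_ds.x)[0] == pytest.approx(0.75)


def test_participation_intercept_matches_share(simple_ds):
    fit = cf.fit_participation_model(simple_ds, learner="intercept")
    assert np.allclose(fit.prob(simple_ds.x), simple_ds.n1 / simple_ds.n)


def test_probability_clipping_contract():
    rng = np.random.default_rng(3)
    n = 200
    x = np.concatenate([rng.normal(-4, 0.5, n), rng.normal(4, 0.5, n)])
    s = np.array([0] * n + [1] * n)
    ds = cf.MultiSourceDataset(y=np.zeros(2 * n), a=np.tile([0, 1], n), s=s,
                               x=pd.DataFrame({"x": x}), xstar_columns=["x"])
    fit = cf.fit_participation_model(ds, clip=(0.001, 0.999))
    p = fit.prob(ds.x)
    assert p.min() >= 0.001 and p.max() <= 0.999
    # the separation is near-complete, so clipping must actually bind
    assert (p <= 0.001).any() and (p >= 0.999).any()


def test_fit_is_invariant_to_row_permutation():
    rng = np.random.default_rng(5)
    n = 60
    ds = make_dataset(
        [(int(i >= n // 2), rng.normal(), int(rng.random() < 0.5), rng.normal())
         for i in range(n)]
    )
    losses = rng.exponential(size=n)
    fit = cf.fit_loss_regression(ds, losses, a=1, source=0, learner="linear")
    perm = rng.permutation(n)
    fit_p = cf.fit_loss_regression(ds.take(perm), losses[perm], a=1, source=0,
                                   learner="linear")
    grid = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
    assert np.allclose(fit.predict(grid), fit_p.predict(grid), atol=1e-8)


def test_logistic_recovers_known_propensity_coefficients():
    from scipy.special import expit

    rng = np.random.default_rng(11)
    n = 40_000
    x = rng.normal(0.5, 1, n)
    a = rng.binomial(1, expit(0.2 + 0.8 * x))
    ds = cf.MultiSourceDataset(
        y=np.zeros(n + 4),
        a=np.concatenate([a, [0, 1, 0, 1]]),
        s=np.array([0] * n + [1] * 4),
        x=pd.DataFrame({"x": np.concatenate([x, np.zeros(4)])}),
        xstar_columns=["x"],
    )
    fit = cf.fit_treatment_model(ds, 0)
    model = fit.learner._model
    assert model.intercept_[0] == pytest.approx(0.2, abs=0.06)
    assert model.coef_[0][0] == pytest.approx(0.8, abs=0.06)


def test_participation_recovers_log_odds_shift():
    # X | S=s ~ N(mu_s, 1) implies logit P(S=1|X) linear with slope mu1-mu0
    rng = np.random.default_rng(13)
    n = 40_000
    x = np.concatenate([rng.normal(0.5, 1, n), rng.normal(0.0, 1, n)])
    s = np.array([0] * n + [1] * n)
    ds = cf.MultiSourceDataset(
        y=np.zeros(2 * n), a=np.tile([0, 1], n), s=s,
        x=pd.DataFrame({"x": x}), xstar_columns=["x"],
    )
    fit = cf.fit_participation_model(ds)
    slope = fit.learner._model.coef_[0][0]
    assert slope == pytest.approx(-0.5, abs=0.05)


def test_pooled_loss_regression_matches_per_source_at_large_n():
    # when the conditional losses agree across sources and the regression
    # is correctly specified, the pooled fit approaches each per-source fit
    cfg = cf.SimulationConfig(n0=20_000, n1=20_000, seed=21)
    ds = cf.generate_dataset(cfg).observed
    losses = cf.compute_losses(ds, cf.true_outcome_model(cfg, 1), "squared_error")
    grid = pd.DataFrame({"x": np.linspace(-1, 2, 7)})
    f0 = cf.fit_loss_regression(ds, losses, 1, 0).predict(grid)
    f1 = cf.fit_loss_regression(ds, losses, 1, 1).predict(grid)
    fp = cf.fit_loss_regression(ds, losses, 1, "pooled").predict(grid)
    assert np.allclose(fp, f0, atol=0.1)
    assert np.allclose(fp, f1, atol=0.1)


def test_cross_fitting_predictions_are_reasonable():
    rng = np.random.default_rng(17)
    n = 400
    ds = make_dataset(
        [(int(i >= n // 2), rng.normal(), 1, rng.normal()) for i in range(n)]
    )
    losses = 2.0 + 1.5 * ds.x["x"].to_numpy() ** 0 + rng.normal(0, 0.1, n)
    fit = cf.fit_loss_regression(ds, losses, a=1, source=0, learner="linear",
                                 cross_fit=5, seed=3)
    assert isinstance(fit.learner, CrossFitRegression)
    preds = fit.predict(ds.x)
    assert np.allclose(preds, 3.5, atol=0.2)


def test_source_homogeneity_diagnostic_flags_shifted_losses():
    from cfrisk.nuisance import source_homogeneity_diagnostic

    cfg = cf.SimulationConfig(n0=4000, n1=4000, seed=51)
    ds = cf.generate_dataset(cfg).observed
    losses = cf.compute_losses(ds, cf.true_outcome_model(cfg, 1), "squared_error")
    # conditional losses agree across sources here: coefficient near zero
    diag = source_homogeneity_diagnostic(ds, losses, a=1)
    assert abs(diag["z"]) < 3.5
    # shift the trial losses and the diagnostic must light up
    shifted = losses + 2.0 * (ds.s == 1)
    diag2 = source_homogeneity_diagnostic(ds, shifted, a=1)
    assert diag2["coef_s"] == pytest.approx(2.0, abs=0.3)
    assert abs(diag2["z"]) > 5


def test_make_learner_rejects_unknown_kind():
    with pytest.raises(DomainError):
        make_learner("deep_net")
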
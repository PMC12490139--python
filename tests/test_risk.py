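"""Risk estimators: losses, hand-computable examples, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

import cfrisk as cf
from cfrisk.exceptions import DomainError

from conftest import make_dataset


@pytest.mark.parametrize(
    "loss, y, g, expected",
    [
        ("squared_error", 2.0, 0.5, 2.25),
        ("absolute", 2.0, 0.5, 1.5),
        ("brier", 1.0, 0.8, 0.04),
        ("squared_error", 3.0, 3.0, 0.0),
        ("absolute", -1.0, -1.0, 0.0),
    ],
)
def test_loss_arithmetic(loss, y, g, expected):
    rows = [(0, 0.0, 1, y), (1, 0.0, 0, y)]
    ds = make_dataset(rows)
    model = cf.PredictionModel(predict=lambda xs: np.full(len(xs), g))
    losses = cf.compute_losses(ds, model, loss)
    assert losses == pytest.approx([expected, expected])


def test_brier_requires_binary_outcome():
    ds = make_dataset([(0, 0.0, 1, 2.0), (1, 0.0, 0, 0.0)])
    model = cf.PredictionModel(predict=lambda xs: np.full(len(xs), 0.5))
    with pytest.raises(DomainError):
        cf.compute_losses(ds, model, "brier")


def test_nonfinite_prediction_rejected():
    ds = make_dataset([(0, 0.0, 1, 2.0), (1, 0.0, 0, 0.0)])
    model = cf.PredictionModel(predict=lambda xs: np.full(len(xs), np.nan))
    with pytest.raises(DomainError):
        cf.compute_losses(ds, model, "squared_error")


class TestOutcomeModelHandExamples:
    """Saturated-fit plug-in estimates on the discrete toy match the
    exhaustive group-by standardization computed independently."""

    def _setup(self, om_toy_dataset, zero_model):
        losses = cf.compute_losses(om_toy_dataset, zero_model, "squared_error")
        nuis = cf.fit_nuisances(
            om_toy_dataset, losses, a_levels=(1,),
            analyses=("observational", "transportability", "joint"),
            estimators=("om",), h_learner="saturated",
        )
        return losses, nuis

    def test_observational_value(self, om_toy_dataset, zero_model):
        losses, nuis = self._setup(om_toy_dataset, zero_model)
        est = cf.estimate_risk_om(om_toy_dataset, losses, 1, "observational", nuis)
        assert est.value == pytest.approx(3.2, abs=1e-10)
        assert est.n_target == 5

    def test_transportability_value(self, om_toy_dataset, zero_model):
        losses, nuis = self._setup(om_toy_dataset, zero_model)
        est = cf.estimate_risk_om(om_toy_dataset, losses, 1, "transportability", nuis)
        assert est.value == pytest.approx(2.2, abs=1e-10)

    def test_matches_brute_force_group_by(self, om_toy_dataset, zero_model):
        """Independent oracle: exhaustive group-by plug-in of the
        identifying functionals."""
        ds = om_toy_dataset
        losses = cf.compute_losses(ds, zero_model, "squared_error")
        frame = pd.DataFrame({"s": ds.s, "a": ds.a, "x": ds.x["x"], "L": losses})

        def plugin(source):
            cell = frame[(frame.s == source) & (frame.a == 1)]
            means = cell.groupby("x")["L"].mean()
            target_x = frame.loc[frame.s == 0, "x"]
            return target_x.map(means).mean()

        losses2, nuis = self._setup(ds, zero_model)
        for analysis, source in (("observational", 0), ("transportability", 1)):
            est = cf.estimate_risk_om(ds, losses2, 1, analysis, nuis)
            assert est.value == pytest.approx(plugin(source), abs=1e-10)


class TestIPWHandExamples:
    def test_observational_weighting(self):
        # S=0: two A=1 rows with losses {2, 4}, two A=0 rows; e_hat = 0.5
        rows = [
            (0, 0.0, 1, math.sqrt(2.0)), (0, 0.0, 1, 2.0),
            (0, 0.0, 0, 0.0), (0, 0.0, 0, 0.0),
            (1, 0.0, 1, 0.0), (1, 0.0, 0, 0.0),
        ]
        ds = make_dataset(rows)
        model = cf.PredictionModel(predict=lambda xs: np.zeros(len(xs)))
        losses = cf.compute_losses(ds, model, "squared_error")
        nuis = cf.fit_nuisances(ds, losses, a_levels=(1,),
                                analyses=("observational",), estimators=("ipw",),
                                e_learner="intercept")
        hajek = cf.estimate_risk_ipw(ds, losses, 1, "observational", nuis)
        ht = cf.estimate_risk_ipw(ds, losses, 1, "observational", nuis,
                                  normalization="ht")
        assert hajek.value == pytest.approx(3.0)
        assert ht.value == pytest.approx(3.0)  # (4 + 8) / n0 with n0 = 4

    def test_transportability_normalization_disagrees_by_design(self):
        # n0 = 2; trial A=1 rows with losses {1, 3}; e = 0.5 known; w = 1
        rows = [
            (0, 0.0, 0, 0.0), (0, 0.0, 1, 0.0),
            (1, 0.0, 1, 1.0), (1, 0.0, 1, math.sqrt(3.0)),
        ]
        ds = make_dataset(rows)
        model = cf.PredictionModel(predict=lambda xs: np.zeros(len(xs)))
        losses = cf.compute_losses(ds, model, "squared_error")
        nuis = cf.fit_nuisances(ds, losses, a_levels=(1,),
                                analyses=("transportability",), estimators=("ipw",),
                                p_learner="intercept", trial_assignment_prob=0.5)
        hajek = cf.estimate_risk_ipw(ds, losses, 1, "transportability", nuis)
        ht = cf.estimate_risk_ipw(ds, losses, 1, "transportability", nuis,
                                  normalization="ht")
        assert hajek.value == pytest.approx(2.0)
        assert ht.value == pytest.approx(4.0)


@pytest.mark.parametrize("analysis", ["observational", "transportability", "joint"])
@pytest.mark.parametrize("estimator", ["om", "ipw", "dr"])
def test_constant_loss_invariance(analysis, estimator):
    """Losses identically c give exactly c for OM, Hajek-IPW and Hajek-DR
    under every analysis."""
    c = 4.2
    rng = np.random.default_rng(1)
    rows = [(s, rng.normal(), a, 0.0) for s in (0, 1) for a in (0, 1)
            for _ in range(6)]
    ds = make_dataset(rows)
    model = cf.PredictionModel(predict=lambda xs: np.zeros(len(xs)))
    losses = np.full(ds.n, c)
    nuis = cf.fit_nuisances(ds, losses, a_levels=(1,), analyses=(analysis,),
                            estimators=(estimator,))
    fn = {"om": cf.estimate_risk_om,
          "ipw": cf.estimate_risk_ipw,
          "dr": cf.estimate_risk_dr}[estimator]
    est = fn(ds, losses, 1, analysis, nuis)
    assert est.value == pytest.approx(c, abs=1e-10)


def test_dr_equals_om_when_h_is_saturated(om_toy_dataset, zero_model):
    """A saturated loss regression fits the cell losses exactly, so every
    residual vanishes and DR collapses to OM."""
    ds = om_toy_dataset
    losses = cf.compute_losses(ds, zero_model, "squared_error")
    nuis = cf.fit_nuisances(ds, losses, a_levels=(1,),
                            analyses=("observational", "transportability"),
                            estimators=("om", "dr"),
                            h_learner="saturated", e_learner="intercept",
                            p_learner="intercept")
    for analysis in ("observational", "transportability"):
        om = cf.estimate_risk_om(ds, losses, 1, analysis, nuis)
        for norm in ("hajek", "ht"):
            dr = cf.estimate_risk_dr(ds, losses, 1, analysis, nuis,
                                     normalization=norm)
            # ht rescales the (zero) correction only, so both match OM
            assert dr.value == pytest.approx(om.value, abs=1e-10)


class TestEstimateRiskTable:
    def test_grid_cardinality(self, om_toy_dataset, zero_model):
        ests, errors = cf.estimate_risk_table(
            om_toy_dataset, zero_model, "squared_error", a_levels=(1,),
            h_learner="saturated", e_learner="intercept", p_learner="intercept",
        )
        assert len(ests) == 9 and not errors

    def test_unestimable_cells_collected_not_fatal(self):
        # no (S=1, A=1) rows: transportability for a=1 must fail, the rest
        # of the grid must still be returned
        rows = [(0, 0.0, 1, 1.0), (0, 0.0, 0, 1.0), (0, 1.0, 1, 2.0),
                (0, 1.0, 0, 0.0), (1, 0.0, 0, 1.0), (1, 1.0, 0, 2.0)]
        ds = make_dataset(rows)
        model = cf.PredictionModel(predict=lambda xs: np.zeros(len(xs)))
        ests, errors = cf.estimate_risk_table(
            ds, model, "squared_error", a_levels=(1,),
            h_learner="linear", e_learner="intercept", p_learner="intercept",
        )
        failed = set(errors)
        assert all(key[1] == "transportability" for key in failed)
        assert {(1, "transportability", e) for e in ("om", "ipw", "dr")} == failed
        assert len(ests) == 6

    def test_constant_losses_full_grid(self):
        rng = np.random.default_rng(2)
        rows = [(s, rng.normal(), a, 3.0) for s in (0, 1) for a in (0, 1)
                for _ in range(5)]
        ds = make_dataset(rows)
        model = cf.PredictionModel(predict=lambda xs: np.zeros(len(xs)))
        ests, errors = cf.estimate_risk_table(
            ds, model, "squared_error", a_levels=(0, 1))
        assert len(ests) == 18 and not errors
        assert all(e.value == pytest.approx(9.0, abs=1e-9) for e in ests)
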
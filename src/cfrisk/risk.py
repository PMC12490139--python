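"""Counterfactual risk estimation in the target population.

The target parameter is the counterfactual risk

    psi(a) = E[ L(Y^a, g(X*)) | S = 0 ],

the expected loss of a prediction model g(X*) in the population
underlying the observational study (S=0) had everyone received treatment
a.  Three analyses identify psi(a) from observed data under different
exchangeability assumptions:

* observational — conditions on (S=0, A=a); requires no unmeasured
  confounding within the observational study;
* transportability — conditions on (S=1, A=a) and reweights/standardizes
  to the S=0 covariate distribution; requires exchangeability of the two
  populations given X;
* joint — pools (A=a) rows from both sources; requires both sets of
  assumptions, in exchange for efficiency.

For each analysis three estimator families are provided: outcome-model
(plug-in of a fitted conditional-loss regression averaged over the target
sample), inverse-probability weighting, and doubly robust (augmented)
estimators that are consistent when either the loss regression or the
weight models are correctly specified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .data import ANALYSES, MultiSourceDataset, validate_cells
from .exceptions import DomainError, EstimabilityError, SchemaError
from .nuisance import NuisanceSet

__all__ = [
    "PredictionModel",
    "LossFunction",
    "RiskEstimate",
    "get_loss",
    "compute_losses",
    "estimate_risk_om",
    "estimate_risk_ipw",
    "estimate_risk_dr",
    "estimate_risk_table",
]


@dataclass
class PredictionModel:
    """The (opaque) model g(X*) under evaluation.

    ``predict`` maps a DataFrame of X* rows to a prediction per row.  The
    model must be fitted on data disjoint from the evaluation rows;
    ``training_provenance`` records where it came from.
    """

    predict: Callable[[pd.DataFrame], np.ndarray]
    description: str = ""
    training_provenance: str = ""

    def predictions(self, xstar_rows: pd.DataFrame) -> np.ndarray:
        preds = np.asarray(self.predict(xstar_rows), dtype=float)
        if preds.shape != (len(xstar_rows),):
            raise DomainError("prediction model must return one value per row")
        if not np.all(np.isfinite(preds)):
            raise DomainError("prediction model produced non-finite values")
        return preds


@dataclass
class LossFunction:
    """A per-row loss L(y, g) comparing outcome and prediction."""

    name: str
    apply: Callable[[np.ndarray, np.ndarray], np.ndarray]


def _brier(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("Brier loss requires a binary 0/1 outcome")
    if np.any((g < 0) | (g > 1)):
        raise DomainError("Brier loss requires predictions in [0, 1]")
    return (y - g) ** 2


_LOSSES = {
    "squared_error": LossFunction("squared_error", lambda y, g: (y - g) ** 2),
    "absolute": LossFunction("absolute", lambda y, g: np.abs(y - g)),
    "brier": LossFunction("brier", _brier),
}
# common aliases
_LOSSES["squared"] = _LOSSES["squared_error"]


def get_loss(loss) -> LossFunction:
    if isinstance(loss, LossFunction):
        return loss
    try:
        return _LOSSES[loss]
    except KeyError:
        raise DomainError(
            f"unknown loss {loss!r}; choose from {sorted(set(_LOSSES))}"
        ) from None


@dataclass
class RiskEstimate:
    """A point estimate of psi(a) with its provenance."""

    a: int
    analysis: str
    estimator: str
    value: float
    n_target: int
    loss: str = ""
    normalization: str = "hajek"
    ci: tuple | None = None  # (lower, upper, level, method)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise DomainError("risk estimate is non-finite")


def compute_losses(ds: MultiSourceDataset, g: PredictionModel, loss) -> np.ndarray:
    """Per-row losses L(Y_i, g(X*_i)) for every row in both sources."""
    loss = get_loss(loss)
    preds = g.predictions(ds.xstar)
    return np.asarray(loss.apply(ds.y, preds), dtype=float)


_H_SOURCE = {"observational": 0, "transportability": 1, "joint": "pooled"}


def estimate_risk_om(
    ds: MultiSourceDataset,
    losses: np.ndarray,
    a: int,
    analysis: str,
    nuis: NuisanceSet,
    loss_name: str = "",
) -> RiskEstimate:
    """Outcome-model (plug-in) estimator.

    Averages the analysis-specific fitted loss regression over the target
    sample: (1/n0) sum_{i: S_i=0} h_hat(X_i), with h_hat = h_{a,0},
    h_{a,1} or the pooled h_a depending on the analysis.
    """
    _check_analysis(analysis)
    target = ds.s == 0
    preds = nuis.h_pred(a, _H_SOURCE[analysis], ds.x[target])
    value = float(np.mean(preds))
    return RiskEstimate(a=a, analysis=analysis, estimator="outcome_model",
                        value=value, n_target=ds.n0, loss=loss_name)


def _check_analysis(analysis: str) -> None:
    if analysis not in ANALYSES:
        raise DomainError(f"analysis must be one of {ANALYSES}, got {analysis!r}")


def _ipw_weights(
    ds: MultiSourceDataset, a: int, analysis: str, nuis: NuisanceSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mask of contributing rows, weight, propensity) per row.

    observational: I(S=0, A=a) / e_a(X; S=0)
    transportability: I(S=1, A=a) * w(X) / e_a(X; S=1)
    joint: I(A=a) * [I(S=0) + I(S=1) w(X)] / e_a(X, S)
    """
    if analysis == "observational":
        mask = (ds.s == 0) & (ds.a == a)
        prop = nuis.prop_a(a, 0, ds.x[mask])
        w = 1.0 / prop
    elif analysis == "transportability":
        mask = (ds.s == 1) & (ds.a == a)
        x = ds.x[mask]
        prop = nuis.prop_a(a, 1, x)
        w = nuis.odds_weight(x) / prop
    else:
        mask = ds.a == a
        x = ds.x[mask]
        s_m = ds.s[mask]
        w = np.empty(int(mask.sum()))
        prop = np.empty_like(w)
        m0 = s_m == 0
        if np.any(m0):
            prop[m0] = nuis.prop_a(a, 0, x[m0])
            w[m0] = 1.0 / prop[m0]
        if np.any(~m0):
            prop[~m0] = nuis.prop_a(a, 1, x[~m0])
            w[~m0] = nuis.odds_weight(x[~m0]) / prop[~m0]
    return mask, w, prop


def _warn_if_clipped(prop: np.ndarray, nuis: NuisanceSet, context: str) -> None:
    """Advisory warning when many weighted rows sit at a clip bound."""
    if prop.size == 0:
        return
    lo, hi = nuis.clip_bounds
    frac = float(np.mean((prop <= lo) | (prop >= hi)))
    if frac > 0.10:
        warnings.warn(
            f"{frac:.0%} of propensities at the clip bounds {nuis.clip_bounds} "
            f"in {context}; weights may be unstable",
            stacklevel=3,
        )


def estimate_risk_ipw(
    ds: MultiSourceDataset,
    losses: np.ndarray,
    a: int,
    analysis: str,
    nuis: NuisanceSet,
    normalization: str = "hajek",
    loss_name: str = "",
) -> RiskEstimate:
    """Inverse-probability-weighting estimator.

    Hajek (default) divides the weighted loss sum by the weight sum, which
    bounds the estimate by the observed loss range and makes it exactly
    invariant for constant losses; ``ht`` (Horvitz-Thompson) divides by n0.
    """
    _check_analysis(analysis)
    _check_normalization(normalization)
    validate_cells(ds, a, analysis)
    mask, w, prop = _ipw_weights(ds, a, analysis, nuis)
    _warn_if_clipped(prop, nuis, f"IPW/{analysis}")
    wl = w * np.asarray(losses, dtype=float)[mask]
    if normalization == "hajek":
        wsum = float(np.sum(w))
        if wsum <= 0:
            raise EstimabilityError("zero weight sum in Hajek IPW estimator")
        value = float(np.sum(wl) / wsum)
    else:
        value = float(np.sum(wl) / ds.n0)
    return RiskEstimate(a=a, analysis=analysis, estimator="ipw", value=value,
                        n_target=ds.n0, loss=loss_name, normalization=normalization)


def _check_normalization(normalization: str) -> None:
    if normalization not in ("hajek", "ht"):
        raise DomainError(f"normalization must be 'hajek' or 'ht', got {normalization!r}")


def estimate_risk_dr(
    ds: MultiSourceDataset,
    losses: np.ndarray,
    a: int,
    analysis: str,
    nuis: NuisanceSet,
    normalization: str = "hajek",
    joint_residual_sources: str = "both",
    loss_name: str = "",
) -> RiskEstimate:
    """Doubly robust (augmented) estimator.

    Outcome-model term plus an inverse-probability-weighted residual
    correction; consistent if either the loss regression or the weight
    models are correctly specified.  ``normalization`` applies to the
    correction term: Hajek divides by the realized weight sum, ``ht`` by
    n0.  For the joint analysis, ``joint_residual_sources`` selects
    whether residuals from both sources or only the trial enter the
    correction.
    """
    _check_analysis(analysis)
    _check_normalization(normalization)
    validate_cells(ds, a, analysis)
    losses = np.asarray(losses, dtype=float)
    target = ds.s == 0
    h_source = _H_SOURCE[analysis]
    om_term = float(np.mean(nuis.h_pred(a, h_source, ds.x[target])))

    mask, w, prop = _ipw_weights(ds, a, analysis, nuis)
    _warn_if_clipped(prop, nuis, f"DR/{analysis}")
    if analysis == "joint" and joint_residual_sources == "trial":
        keep = ds.s[mask] == 1
        w = w[keep]
        mask = mask & (ds.s == 1)
    elif analysis == "joint" and joint_residual_sources != "both":
        raise DomainError("joint_residual_sources must be 'both' or 'trial'")
    resid = losses[mask] - nuis.h_pred(a, h_source, ds.x[mask])
    if normalization == "hajek":
        wsum = float(np.sum(w))
        if wsum <= 0:
            raise EstimabilityError("zero weight sum in Hajek DR correction")
        corr = float(np.sum(w * resid) / wsum)
    else:
        corr = float(np.sum(w * resid) / ds.n0)
    return RiskEstimate(a=a, analysis=analysis, estimator="dr", value=om_term + corr,
                        n_target=ds.n0, loss=loss_name, normalization=normalization)


_ESTIMATOR_FN = {
    "om": lambda ds, L, a, an, nu, norm, ln: estimate_risk_om(ds, L, a, an, nu, loss_name=ln),
    "ipw": lambda ds, L, a, an, nu, norm, ln: estimate_risk_ipw(
        ds, L, a, an, nu, normalization=norm, loss_name=ln
    ),
    "dr": lambda ds, L, a, an, nu, norm, ln: estimate_risk_dr(
        ds, L, a, an, nu, normalization=norm, loss_name=ln
    ),
}


def estimate_risk_table(
    ds: MultiSourceDataset,
    g: PredictionModel,
    loss,
    a_levels=(0, 1),
    analyses=ANALYSES,
    estimators=("om", "ipw", "dr"),
    nuis: NuisanceSet | None = None,
    normalization: str = "hajek",
    **nuisance_kwargs,
) -> tuple[list[RiskEstimate], dict]:
    """Compute the full estimate grid from shared nuisance fits.

    Returns ``(estimates, errors)`` where ``errors`` maps the
    (a, analysis, estimator) combinations that failed to their
    estimability errors; failures in one cell do not abort the others.
    """
    from .exceptions import StateError
    from .nuisance import (
        NuisanceSet as _NuisanceSet,
        _required_pieces,
        fit_loss_regression,
        fit_participation_model,
        fit_treatment_model,
    )

    loss_fn = get_loss(loss)
    losses = compute_losses(ds, g, loss_fn)
    errors: dict = {}
    if nuis is None:
        # fit each required piece independently so one empty cell does not
        # abort the rest of the grid; estimators depending on a failed
        # piece raise StateError below and are recorded
        h_learner = nuisance_kwargs.pop("h_learner", "linear")
        e_learner = nuisance_kwargs.pop("e_learner", "logistic")
        p_learner = nuisance_kwargs.pop("p_learner", "logistic")
        clip = nuisance_kwargs.pop("clip", None)
        trial_prob = nuisance_kwargs.pop("trial_assignment_prob", None)
        cross_fit = nuisance_kwargs.pop("cross_fit", 0)
        seed = nuisance_kwargs.pop("seed", 0)
        nuis = _NuisanceSet(trial_assignment_prob=trial_prob)
        if clip is not None:
            nuis.clip_bounds = clip
        else:
            clip = nuis.clip_bounds
        need_h, need_e, need_p = _required_pieces(analyses, estimators, a_levels)
        for a, source in sorted(need_h, key=str):
            try:
                nuis.h[(a, source)] = fit_loss_regression(
                    ds, losses, a, source, learner=h_learner,
                    cross_fit=cross_fit, seed=seed,
                )
            except EstimabilityError:
                pass
        for source in sorted(need_e):
            if source == 1 and trial_prob is not None:
                continue
            try:
                nuis.e[source] = fit_treatment_model(ds, source, learner=e_learner, clip=clip)
            except EstimabilityError:
                pass
        if need_p:
            nuis.participation = fit_participation_model(ds, learner=p_learner, clip=clip)
    estimates: list[RiskEstimate] = []
    for a in a_levels:
        for analysis in analyses:
            for est in estimators:
                try:
                    estimates.append(
                        _ESTIMATOR_FN[est](ds, losses, a, analysis, nuis,
                                           normalization, loss_fn.name)
                    )
                except (EstimabilityError, StateError) as err:
                    errors[(a, analysis, est)] = err
    return estimates, errors
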
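"""Nuisance-function estimation.

Every risk estimator consumes some subset of three nuisance functions:

* outcome-loss regressions ``h_{a,s}(X)`` estimating
  E[L(Y, g(X*)) | X, S=s, A=a] (and the pooled ``h_a(X)`` estimating
  E[L(Y, g(X*)) | X, A=a], which omits S because under the joint-analysis
  assumptions the conditional losses are equal across sources);
* treatment propensities Pr(A=1 | X, S=s) per source;
* the trial-participation model Pr(S=1 | X) on the combined sample, whose
  implied odds w(X) = Pr(S=0|X)/Pr(S=1|X) is the transport weight of the
  non-nested design (identified only up to the unknown sampling fractions,
  a constant absorbed by Hajek normalization).

All probability outputs are clipped into ``clip_bounds`` to stabilize
weights.  Optional K-fold cross-fitting is available for flexible learners;
the parametric defaults do not use it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultiSourceDataset
from .exceptions import DomainError, EstimabilityError, StateError
from .learners import make_learner

__all__ = [
    "DEFAULT_CLIP",
    "FittedRegression",
    "FittedPropensity",
    "NuisanceSet",
    "fit_loss_regression",
    "fit_treatment_model",
    "fit_participation_model",
    "fit_nuisances",
    "source_homogeneity_diagnostic",
]

DEFAULT_CLIP = (0.001, 0.999)


def _cell_mask(ds: MultiSourceDataset, a: int | None, source) -> np.ndarray:
    mask = np.ones(ds.n, dtype=bool)
    if source != "pooled":
        mask &= ds.s == int(source)
    if a is not None:
        mask &= ds.a == int(a)
    return mask


@dataclass
class FittedRegression:
    """A fitted conditional-mean regression with row provenance."""

    learner: object
    columns: list[str]
    rows_used: np.ndarray

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        preds = np.asarray(self.learner.predict(x[self.columns]), dtype=float)
        if not np.all(np.isfinite(preds)):
            raise DomainError("loss regression produced non-finite predictions")
        return preds


class CrossFitRegression:
    """K-fold cross-fitted regression.

    In-cell rows receive held-out predictions (the model fitted on the
    other folds); arbitrary external rows receive the average over fold
    models.  Fold assignment is deterministic given ``seed``.
    """

    def __init__(self, learner_spec, k: int, seed: int = 0) -> None:
        self.learner_spec = learner_spec
        self.k = int(k)
        self.seed = seed
        self.models_: list | None = None
        self.fold_of_row_: dict[int, int] | None = None

    def fit(self, x: pd.DataFrame, y: np.ndarray, rows: np.ndarray):
        if self.k < 2:
            raise DomainError("cross-fitting requires k >= 2 folds")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(rows))
        folds = np.array_split(order, self.k)
        self.models_ = []
        self.fold_of_row_ = {}
        for j, fold in enumerate(folds):
            train = np.setdiff1d(np.arange(len(rows)), fold)
            model = make_learner(self.learner_spec)
            model.fit(x.iloc[train], y[train])
            self.models_.append(model)
            for i in fold:
                self.fold_of_row_[int(rows[i])] = j
        self._x_fit = x
        self._rows = rows
        return self

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        if self.models_ is None:
            raise StateError("CrossFitRegression used before fitting")
        preds = np.mean([m.predict(x) for m in self.models_], axis=0)
        return np.asarray(preds, dtype=float)


@dataclass
class FittedPropensity:
    """A fitted probability model with clipping."""

    learner: object
    columns: list[str]
    rows_used: np.ndarray
    clip_bounds: tuple[float, float] = DEFAULT_CLIP
    constant: float | None = None  # known probability (e.g. trial randomization)

    def prob(self, x: pd.DataFrame) -> np.ndarray:
        if self.constant is not None:
            p = np.full(len(x), self.constant)
        else:
            p = np.asarray(self.learner.predict(x[self.columns]), dtype=float)
        lo, hi = self.clip_bounds
        return np.clip(p, lo, hi)


def fit_loss_regression(
    ds: MultiSourceDataset,
    losses: np.ndarray,
    a: int,
    source,
    learner="linear",
    cross_fit: int = 0,
    seed: int = 0,
) -> FittedRegression:
    """Fit E[L(Y, g(X*)) | X, S=source, A=a] on the designated cell.

    ``source`` is 0, 1 or ``"pooled"`` (all A=a rows across sources).
    The regression targets the per-row loss directly, matching the risk
    functional being estimated.
    """
    losses = np.asarray(losses, dtype=float)
    if len(losses) != ds.n:
        raise DomainError("losses must have one entry per dataset row")
    mask = _cell_mask(ds, a, source)
    if not np.all(np.isfinite(losses[mask])):
        raise DomainError("non-finite losses in the fitting cell")
    if not np.any(mask):
        raise EstimabilityError(f"empty cell (source={source}, A={a}) for loss regression")
    rows = np.flatnonzero(mask)
    cols = list(ds.x.columns)
    if cross_fit:
        model = CrossFitRegression(learner, cross_fit, seed=seed)
        model.fit(ds.x.iloc[rows], losses[rows], rows)
    else:
        model = make_learner(learner)
        model.fit(ds.x.iloc[rows], losses[rows])
    return FittedRegression(learner=model, columns=cols, rows_used=rows)


def fit_treatment_model(
    ds: MultiSourceDataset,
    source: int,
    learner="logistic",
    clip: tuple[float, float] = DEFAULT_CLIP,
) -> FittedPropensity:
    """Fit the treatment propensity Pr(A=1 | X, S=source)."""
    mask = ds.s == int(source)
    if not np.any(mask):
        raise EstimabilityError(f"source stratum S={source} is empty")
    a_cell = ds.a[mask]
    if np.unique(a_cell).size < 2:
        raise EstimabilityError(
            f"single treatment level in stratum S={source}; propensity not estimable"
        )
    rows = np.flatnonzero(mask)
    model = make_learner(learner)
    model.fit(ds.x.iloc[rows], a_cell)
    return FittedPropensity(
        learner=model, columns=list(ds.x.columns), rows_used=rows, clip_bounds=clip
    )


def fit_participation_model(
    ds: MultiSourceDataset,
    learner="logistic",
    clip: tuple[float, float] = DEFAULT_CLIP,
) -> FittedPropensity:
    """Fit the participation model Pr(S=1 | X) on the combined sample."""
    model = make_learner(learner)
    model.fit(ds.x, ds.s)
    return FittedPropensity(
        learner=model,
        columns=list(ds.x.columns),
        rows_used=np.arange(ds.n),
        clip_bounds=clip,
    )


@dataclass
class NuisanceSet:
    """Container for the fitted nuisance functions an estimator needs.

    ``h`` is keyed by ``(a, source)`` with source in {0, 1, "pooled"};
    ``e`` is keyed by source.  ``trial_assignment_prob``, when supplied,
    fixes the trial-stratum propensity to the known randomization
    probability instead of an estimate.
    """

    clip_bounds: tuple[float, float] = DEFAULT_CLIP
    h: dict = field(default_factory=dict)
    e: dict = field(default_factory=dict)
    participation: FittedPropensity | None = None
    trial_assignment_prob: float | None = None

    # -- prediction helpers -------------------------------------------
    def h_pred(self, a: int, source, x: pd.DataFrame) -> np.ndarray:
        key = (int(a), source if source == "pooled" else int(source))
        if key not in self.h:
            raise StateError(f"loss regression h for cell {key} not fitted")
        return self.h[key].predict(x)

    def prop_a(self, a: int, source: int, x: pd.DataFrame) -> np.ndarray:
        """Propensity of receiving the *requested* level a within a source."""
        source = int(source)
        if source == 1 and self.trial_assignment_prob is not None:
            p1 = np.full(len(x), float(self.trial_assignment_prob))
        else:
            if source not in self.e:
                raise StateError(f"treatment propensity for source S={source} not fitted")
            p1 = self.e[source].prob(x)
        p = p1 if int(a) == 1 else 1.0 - p1
        lo, hi = self.clip_bounds
        return np.clip(p, lo, hi)

    def odds_weight(self, x: pd.DataFrame) -> np.ndarray:
        """Transport odds w(X) = Pr(S=0 | X) / Pr(S=1 | X)."""
        if self.participation is None:
            raise StateError("participation model not fitted")
        p1 = self.participation.prob(x)
        return (1.0 - p1) / p1


def source_homogeneity_diagnostic(
    ds: MultiSourceDataset, losses: np.ndarray, a: int
) -> dict:
    """Diagnostic refit of the pooled loss regression with S as a predictor.

    The joint analysis pools the two sources because it assumes the
    conditional expected losses agree across them; that equality is a
    statement about observed data and can be probed.  This fits an OLS of
    the loss on (X, S) among A=a rows and reports the coefficient on S
    with a conventional standard error — a materially nonzero coefficient
    argues against pooling.  Advisory only.
    """
    mask = _cell_mask(ds, a, "pooled")
    if not np.any(ds.s[mask] == 0) or not np.any(ds.s[mask] == 1):
        raise EstimabilityError(f"both sources need A={a} rows for the diagnostic")
    losses = np.asarray(losses, dtype=float)
    x = ds.x[mask].to_numpy(dtype=float)
    z = np.column_stack([np.ones(mask.sum()), x, ds.s[mask]])
    y = losses[mask]
    coef, *_ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ coef
    dof = max(len(y) - z.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(z.T @ z)
    se = float(np.sqrt(cov[-1, -1]))
    return {"coef_s": float(coef[-1]), "se": se,
            "z": float(coef[-1] / se) if se > 0 else np.inf,
            "n": int(mask.sum())}


def _required_pieces(analyses, estimators, a_levels):
    need_h, need_e, need_p = set(), set(), False
    for analysis in analyses:
        for est in estimators:
            for a in a_levels:
                if est in ("om", "dr"):
                    if analysis == "observational":
                        need_h.add((a, 0))
                    elif analysis == "transportability":
                        need_h.add((a, 1))
                    else:
                        need_h.add((a, "pooled"))
                if est in ("ipw", "dr"):
                    if analysis == "observational":
                        need_e.add(0)
                    elif analysis == "transportability":
                        need_e.add(1)
                        need_p = True
                    else:
                        need_e.update((0, 1))
                        need_p = True
    return need_h, need_e, need_p


def fit_nuisances(
    ds: MultiSourceDataset,
    losses: np.ndarray | None = None,
    a_levels=(1,),
    analyses=("observational", "transportability", "joint"),
    estimators=("om", "ipw", "dr"),
    h_learner="linear",
    e_learner="logistic",
    p_learner="logistic",
    clip: tuple[float, float] = DEFAULT_CLIP,
    trial_assignment_prob: float | None = None,
    cross_fit: int = 0,
    seed: int = 0,
) -> NuisanceSet:
    """Fit exactly the nuisance functions the requested estimators need.

    ``trial_assignment_prob`` short-circuits estimation of the trial
    propensity with the known randomization probability.
    """
    need_h, need_e, need_p = _required_pieces(analyses, estimators, a_levels)
    nuis = NuisanceSet(clip_bounds=clip, trial_assignment_prob=trial_assignment_prob)
    if need_h:
        if losses is None:
            raise DomainError("losses are required to fit loss regressions")
        for a, source in sorted(need_h, key=str):
            nuis.h[(a, source)] = fit_loss_regression(
                ds, losses, a, source, learner=h_learner, cross_fit=cross_fit, seed=seed
            )
    for source in sorted(need_e):
        if source == 1 and trial_assignment_prob is not None:
            continue  # known randomization probability, nothing to fit
        nuis.e[source] = fit_treatment_model(ds, source, learner=e_learner, clip=clip)
    if need_p:
        nuis.participation = fit_participation_model(ds, learner=p_learner, clip=clip)
    return nuis
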
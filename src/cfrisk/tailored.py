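"""Tailored models for the conditional counterfactual mean.

A *tailored model* estimates mu_a(X*) = E[Y^a | X*, S=0], the conditional
mean of the potential outcome under treatment a, given the model
covariates X*, in the target population.  Each analysis identifies
mu_a(X*) as an iterated expectation

    mu_a(X*) = E[ E[Y | X, cell] | X*, S=0 ]

where the inner conditioning cell is (S=0, A=a) for the observational
analysis, (S=1, A=a) for the transportability analysis, and (A=a) pooled
across sources for the joint analysis.  This suggests the two-step fit
implemented here: step 1 regresses Y on the full covariate set X within
the cell; step 2 regresses the step-1 predictions, evaluated on every
target (S=0) row, on X* among those target rows.  Step 2 uses
squared-error regression throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ANALYSES, MultiSourceDataset, validate_cells
from .exceptions import DomainError, SchemaError
from .learners import make_learner
from .nuisance import _cell_mask

__all__ = ["TailoredModel", "fit_tailored_model", "predict_tailored"]

_CELL_SOURCE = {"observational": 0, "transportability": 1, "joint": "pooled"}


@dataclass
class TailoredModel:
    """A fitted two-step estimator of mu_a(X*)."""

    a: int
    analysis: str
    step1_model: object
    step2_model: object
    x_columns: list[str]
    xstar_columns: list[str]

    def predict(self, xstar_rows: pd.DataFrame) -> np.ndarray:
        return predict_tailored(self, xstar_rows)


def fit_tailored_model(
    ds: MultiSourceDataset,
    a: int,
    analysis: str,
    learner1="linear",
    learner2="linear",
) -> TailoredModel:
    """Fit the two-step tailored model for mu_a(X*) under an analysis.

    Step 1 fits E[Y | X] in the analysis-specific cell; step 2 generates
    step-1 predictions for *all* target rows (regardless of their observed
    treatment) and regresses them on X* among those rows.
    """
    if analysis not in ANALYSES:
        raise DomainError(f"analysis must be one of {ANALYSES}, got {analysis!r}")
    if not ds.xstar_columns:
        raise DomainError("xstar_columns is empty; a tailored model needs X*")
    validate_cells(ds, a, analysis)
    cell = _cell_mask(ds, a, _CELL_SOURCE[analysis])
    step1 = make_learner(learner1)
    step1.fit(ds.x[cell], ds.y[cell])

    target = ds.s == 0
    step1_preds = np.asarray(step1.predict(ds.x[target]), dtype=float)
    step2 = make_learner(learner2)
    step2.fit(ds.xstar[target], step1_preds)
    return TailoredModel(
        a=a,
        analysis=analysis,
        step1_model=step1,
        step2_model=step2,
        x_columns=list(ds.x.columns),
        xstar_columns=list(ds.xstar_columns),
    )


def predict_tailored(model: TailoredModel, xstar_rows: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted tailored model on X* rows (row-wise, order kept)."""
    if isinstance(xstar_rows, pd.DataFrame):
        missing = [c for c in model.xstar_columns if c not in xstar_rows.columns]
        if missing:
            raise SchemaError(f"xstar rows are missing columns {missing}")
        xstar_rows = xstar_rows[model.xstar_columns]
    preds = np.asarray(model.step2_model.predict(xstar_rows), dtype=float)
    if not np.all(np.isfinite(preds)):
        raise DomainError("tailored model produced non-finite predictions")
    return preds
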
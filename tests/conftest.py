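"""Shared fixtures: small hand-constructed datasets with known algebra."""

import math

import numpy as np
import pandas as pd
import pytest

from cfrisk import MultiSourceDataset, PredictionModel


def make_dataset(rows, xstar=None):
    """Build a dataset from (s, x, a, y) tuples; x may be a tuple for
    multi-column covariates."""
    s, x, a, y = zip(*rows)
    x0 = x[0]
    if isinstance(x0, tuple):
        xmat = pd.DataFrame(list(x), columns=[f"x{i+1}" for i in range(len(x0))])
    else:
        xmat = pd.DataFrame({"x": list(x)})
    return MultiSourceDataset(
        y=np.array(y, dtype=float),
        a=np.array(a),
        s=np.array(s),
        x=xmat,
        xstar_columns=list(xstar) if xstar is not None else list(xmat.columns),
    )


@pytest.fixture
def zero_model():
    """g(x*) = 0, so squared-error losses equal Y^2."""
    return PredictionModel(predict=lambda xs: np.zeros(len(xs)),
                           description="zero predictor")


@pytest.fixture
def om_toy_dataset():
    """Discrete toy with known group means.

    With g = 0 and squared error, losses are Y^2.  The (S=0, A=1) cell has
    losses {1, 3} at X=0 and {5} at X=1 (means 2 and 5); the (S=1, A=1)
    cell has losses {1} at X=0 and {4} at X=1.  S=0 X-counts are
    {X=0: 3, X=1: 2}, so the saturated outcome-model estimates are
    psi_obs = (3*2 + 2*5)/5 = 3.2 and psi_tr = (3*1 + 2*4)/5 = 2.2.
    """
    rows = [
        # (s, x, a, y)
        (0, 0.0, 1, 1.0),
        (0, 0.0, 1, math.sqrt(3.0)),
        (0, 0.0, 0, 0.0),
        (0, 1.0, 1, math.sqrt(5.0)),
        (0, 1.0, 0, 0.0),
        (1, 0.0, 1, 1.0),
        (1, 1.0, 1, 2.0),
        (1, 0.0, 0, 0.0),
        (1, 1.0, 0, 0.0),
    ]
    return make_dataset(rows)
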
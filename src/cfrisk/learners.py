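"""Regression and classification learners used for nuisance functions.

Every learner satisfies a minimal fit/predict contract:

* ``fit(X, y) -> self`` where ``X`` is a 2-D array or DataFrame of numeric
  features and ``y`` a 1-D response;
* ``predict(X) -> ndarray`` returning one value per row, deterministically
  given the fitted state (tree learners carry an explicit seed).

For probability models (treatment propensity, trial participation) the
``predict`` output is the probability of the positive class.  Learners are
intentionally thin: anything with the same contract can be passed wherever
a learner is accepted (``user_supplied`` kind).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError, EstimabilityError

__all__ = [
    "LinearLearner",
    "InterceptOnlyLearner",
    "LogisticLearner",
    "RandomForestLearner",
    "SaturatedLearner",
    "make_learner",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


class LinearLearner:
    """Main-effects ordinary least squares with an intercept.

    Implemented directly with :func:`numpy.linalg.lstsq` because it sits on
    the hot path of the bootstrap (tens of thousands of refits).
    """

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        Z = np.column_stack([np.ones(len(X)), X])
        self.coef_, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return self

    def predict(self, X) -> np.ndarray:
        if self.coef_ is None:
            raise EstimabilityError("LinearLearner used before fitting")
        X = _as_matrix(X)
        return np.column_stack([np.ones(len(X)), X]) @ self.coef_


class QuadraticLearner(LinearLearner):
    """OLS on a degree-2 polynomial basis (main effects, squares and
    pairwise products).

    The natural loss-regression specification when the evaluated model and
    the outcome mean are both linear in X: the squared-error loss surface
    is then exactly quadratic.
    """

    def _expand(self, X: np.ndarray) -> np.ndarray:
        cols = [X]
        d = X.shape[1]
        for i in range(d):
            for j in range(i, d):
                cols.append((X[:, i] * X[:, j])[:, None])
        return np.hstack(cols)

    def fit(self, X, y):
        return super().fit(self._expand(_as_matrix(X)), y)

    def predict(self, X) -> np.ndarray:
        return super().predict(self._expand(_as_matrix(X)))


class InterceptOnlyLearner:
    """Predicts the training mean everywhere.

    Used as a deliberately coarse (typically misspecified) nuisance model in
    robustness studies, and as a degenerate propensity model.
    """

    def __init__(self) -> None:
        self.mean_: float | None = None

    def fit(self, X, y):
        self.mean_ = float(np.mean(np.asarray(y, dtype=float)))
        return self

    def predict(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise EstimabilityError("InterceptOnlyLearner used before fitting")
        return np.full(len(_as_matrix(X)), self.mean_)


class LogisticLearner:
    """Main-effects logistic regression returning P(y=1 | X).

    Unpenalized maximum likelihood (scikit-learn with an infinite inverse
    penalty), matching the main-effect logistic nuisance models used as
    defaults throughout.
    """

    def __init__(self, max_iter: int = 200) -> None:
        self.max_iter = max_iter
        self._model = None
        self._constant: float | None = None

    def fit(self, X, y):
        from sklearn.linear_model import LogisticRegression

        X = _as_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise EstimabilityError(
                f"logistic fit needs both classes; response is constant ({classes!r})"
            )
        self._model = LogisticRegression(C=np.inf, max_iter=self.max_iter)
        self._model.fit(X, y.astype(int))
        return self

    def predict(self, X) -> np.ndarray:
        if self._model is None:
            raise EstimabilityError("LogisticLearner used before fitting")
        return self._model.predict_proba(_as_matrix(X))[:, 1]


class RandomForestLearner:
    """Random forest regression (or probability prediction for 0/1 responses).

    Carries an explicit ``seed`` so fitted predictions are reproducible.
    """

    def __init__(self, seed: int = 0, n_estimators: int = 200, **kwargs) -> None:
        self.seed = seed
        self.n_estimators = n_estimators
        self.kwargs = kwargs
        self._model = None
        self._is_classifier = False

    def fit(self, X, y):
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        X = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        binary = set(np.unique(y)) <= {0.0, 1.0}
        if binary and np.unique(y).size == 2:
            self._model = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.seed, **self.kwargs
            )
            self._model.fit(X, y.astype(int))
            self._is_classifier = True
        else:
            self._model = RandomForestRegressor(
                n_estimators=self.n_estimators, random_state=self.seed, **self.kwargs
            )
            self._model.fit(X, y)
            self._is_classifier = False
        return self

    def predict(self, X) -> np.ndarray:
        if self._model is None:
            raise EstimabilityError("RandomForestLearner used before fitting")
        X = _as_matrix(X)
        if self._is_classifier:
            return self._model.predict_proba(X)[:, 1]
        return self._model.predict(X)


class SaturatedLearner:
    """Fully saturated fit on discrete covariates: one cell mean per
    distinct covariate pattern.

    Exists to make exact finite-sample algebra possible (group-by-mean
    oracles); prediction at a pattern unseen during fitting is an
    estimability error rather than an extrapolation.
    """

    def __init__(self) -> None:
        self.means_: dict[tuple, float] | None = None

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float)
        means: dict[tuple, list[float]] = {}
        for row, val in zip(X, y):
            means.setdefault(tuple(row), []).append(float(val))
        self.means_ = {k: float(np.mean(v)) for k, v in means.items()}
        return self

    def predict(self, X) -> np.ndarray:
        if self.means_ is None:
            raise EstimabilityError("SaturatedLearner used before fitting")
        X = _as_matrix(X)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            key = tuple(row)
            if key not in self.means_:
                raise EstimabilityError(
                    f"covariate pattern {key} not observed in the fitting cell"
                )
            out[i] = self.means_[key]
        return out


_KINDS = {
    "linear": LinearLearner,
    "quadratic": QuadraticLearner,
    "intercept": InterceptOnlyLearner,
    "logistic": LogisticLearner,
    "random_forest": RandomForestLearner,
    "saturated": SaturatedLearner,
}


def make_learner(spec, **hyperparameters):
    """Instantiate a learner from a kind name, or pass an instance through.

    Parameters
    ----------
    spec
        Either one of ``{"linear", "intercept", "logistic", "random_forest",
        "saturated"}`` or any object with ``fit``/``predict`` methods
        (a user-supplied learner).
    """
    if isinstance(spec, str):
        try:
            cls = _KINDS[spec]
        except KeyError:
            raise DomainError(
                f"unknown learner kind {spec!r}; choose from {sorted(_KINDS)}"
            ) from None
        return cls(**hyperparameters)
    if hasattr(spec, "fit") and hasattr(spec, "predict"):
        return spec
    raise DomainError(f"{spec!r} is neither a learner kind nor a fit/predict object")
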
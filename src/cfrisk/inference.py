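"""Bootstrap inference and benchmarking.

Uncertainty for any risk estimate comes from a nonparametric bootstrap
stratified by source: each replicate resamples n0 rows (with replacement)
from the observational stratum and n1 rows from the trial stratum —
matching the non-nested design in which the two sample sizes are fixed —
and refits every nuisance function before recomputing the estimate.

Benchmarking compares the observational and transportability estimates of
the same counterfactual risk.  The paired difference
delta = psi_obs - psi_tr is bootstrapped with the *same* resample feeding
both analyses within a replicate, so its distribution reflects estimator
disagreement rather than sampling differences.  A confidence interval for
delta containing zero is reported as concordance; concordance supports,
but cannot prove, the identifying assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import MultiSourceDataset
from .exceptions import EstimabilityError
from .nuisance import DEFAULT_CLIP, fit_nuisances
from .risk import (
    PredictionModel,
    compute_losses,
    estimate_risk_dr,
    estimate_risk_ipw,
    estimate_risk_om,
    get_loss,
)

__all__ = ["EstimatorSpec", "BootstrapResult", "BenchmarkResult",
           "bootstrap_estimate", "benchmark"]


@dataclass
class EstimatorSpec:
    """A complete, self-contained estimation recipe.

    Bundles everything needed to turn a dataset into a single number:
    treatment level, analysis, estimator family, loss, the model under
    evaluation, and the nuisance-learner configuration.  ``estimate``
    refits all nuisances from scratch, which is what the bootstrap needs.
    """

    a: int
    analysis: str
    estimator: str  # om | ipw | dr
    loss: object
    model: PredictionModel
    normalization: str = "hajek"
    h_learner: object = "linear"
    e_learner: object = "logistic"
    p_learner: object = "logistic"
    clip: tuple[float, float] = DEFAULT_CLIP
    trial_assignment_prob: float | None = None
    cross_fit: int = 0
    joint_residual_sources: str = "both"

    def estimate(self, ds: MultiSourceDataset) -> float:
        loss_fn = get_loss(self.loss)
        losses = compute_losses(ds, self.model, loss_fn)
        nuis = fit_nuisances(
            ds,
            losses,
            a_levels=(self.a,),
            analyses=(self.analysis,),
            estimators=(self.estimator,),
            h_learner=self.h_learner,
            e_learner=self.e_learner,
            p_learner=self.p_learner,
            clip=self.clip,
            trial_assignment_prob=self.trial_assignment_prob,
            cross_fit=self.cross_fit,
        )
        if self.estimator == "om":
            est = estimate_risk_om(ds, losses, self.a, self.analysis, nuis,
                                   loss_name=loss_fn.name)
        elif self.estimator == "ipw":
            est = estimate_risk_ipw(ds, losses, self.a, self.analysis, nuis,
                                    normalization=self.normalization,
                                    loss_name=loss_fn.name)
        elif self.estimator == "dr":
            est = estimate_risk_dr(ds, losses, self.a, self.analysis, nuis,
                                   normalization=self.normalization,
                                   joint_residual_sources=self.joint_residual_sources,
                                   loss_name=loss_fn.name)
        else:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        return est.value


@dataclass
class BootstrapResult:
    """Replicate values, SE and CI for one estimation recipe."""

    point_estimate: float
    replicate_values: np.ndarray
    se: float
    ci: tuple[float, float]
    ci_method: str
    level: float
    B: int
    seed: int
    n_failed: int = 0


@dataclass
class BenchmarkResult:
    """Observational-vs-transportability comparison of one risk."""

    delta: float
    ci: tuple[float, float]
    concordant: bool
    level: float
    psi_obs: float
    psi_tr: float
    se: float
    B: int
    seed: int
    narrative: str = (
        "Concordance (the interval for psi_obs - psi_tr containing zero) "
        "supports the identifying assumptions but does not guarantee their "
        "validity: both analyses could be biased in the same direction. "
        "Judgement should also weigh subject-matter knowledge and the "
        "clinical relevance of the difference."
    )


def _stratified_indices(rng: np.random.Generator, s: np.ndarray) -> np.ndarray:
    """Resample row indices with replacement within each source stratum."""
    idx0 = np.flatnonzero(s == 0)
    idx1 = np.flatnonzero(s == 1)
    draw0 = rng.choice(idx0, size=idx0.size, replace=True)
    draw1 = rng.choice(idx1, size=idx1.size, replace=True)
    return np.concatenate([draw0, draw1])


def _ci_from_replicates(point, reps, level, ci_method):
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    if ci_method == "wald":
        z = stats.norm.ppf(0.5 + level / 2)
        ci = (point - z * se, point + z * se)
    elif ci_method == "percentile":
        alpha = 1 - level
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"ci_method must be 'wald' or 'percentile', got {ci_method!r}")
    return se, ci


def bootstrap_estimate(
    ds: MultiSourceDataset,
    spec: EstimatorSpec,
    B: int = 500,
    seed: int = 0,
    ci_method: str = "wald",
    level: float = 0.95,
    max_retries: int = 10,
) -> BootstrapResult:
    """Source-stratified nonparametric bootstrap of one estimation recipe.

    Nuisances are refit inside every replicate, so the interval reflects
    their estimation error.  A replicate whose resample is degenerate
    (estimability failure) is redrawn up to ``max_retries`` times, then
    counted as failed; more than 5% failures triggers a warning.
    """
    point = spec.estimate(ds)
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    n_failed = 0
    for b in range(B):
        value = None
        for _ in range(max_retries + 1):
            idx = _stratified_indices(rng, ds.s)
            try:
                value = spec.estimate(ds.take(idx))
                break
            except EstimabilityError:
                continue
        if value is None:
            n_failed += 1
            reps[b] = np.nan
        else:
            reps[b] = value
    reps = reps[np.isfinite(reps)]
    if n_failed > 0.05 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed even after retries",
            stacklevel=2,
        )
    se, ci = _ci_from_replicates(point, reps, level, ci_method)
    return BootstrapResult(
        point_estimate=point, replicate_values=reps, se=se, ci=ci,
        ci_method=ci_method, level=level, B=B, seed=seed, n_failed=n_failed,
    )


def benchmark(
    ds: MultiSourceDataset,
    g: PredictionModel,
    loss,
    a: int,
    estimator: str = "om",
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
    ci_method: str = "wald",
    max_retries: int = 10,
    **spec_kwargs,
) -> BenchmarkResult:
    """Benchmark the observational against the transportability estimate.

    Computes delta = psi_obs - psi_tr on the original data, then
    bootstraps the paired difference: within each replicate both analyses
    see the identical stratified resample.
    """
    spec_obs = EstimatorSpec(a=a, analysis="observational", estimator=estimator,
                             loss=loss, model=g, **spec_kwargs)
    spec_tr = replace(spec_obs, analysis="transportability")
    psi_obs = spec_obs.estimate(ds)
    psi_tr = spec_tr.estimate(ds)
    delta = psi_obs - psi_tr

    rng = np.random.default_rng(seed)
    reps = []
    n_failed = 0
    for _ in range(B):
        value = None
        for _retry in range(max_retries + 1):
            idx = _stratified_indices(rng, ds.s)
            boot = ds.take(idx)
            try:
                value = spec_obs.estimate(boot) - spec_tr.estimate(boot)
                break
            except EstimabilityError:
                continue
        if value is None:
            n_failed += 1
        else:
            reps.append(value)
    if n_failed > 0.05 * B:
        warnings.warn(
            f"{n_failed}/{B} benchmark replicates failed even after retries",
            stacklevel=2,
        )
    reps = np.asarray(reps)
    se, ci = _ci_from_replicates(delta, reps, level, ci_method)
    concordant = bool(ci[0] <= 0.0 <= ci[1])
    return BenchmarkResult(
        delta=delta, ci=ci, concordant=concordant, level=level,
        psi_obs=psi_obs, psi_tr=psi_tr, se=se, B=B, seed=seed,
    )
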
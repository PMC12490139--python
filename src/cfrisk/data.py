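"""Multi-source dataset container, loading, validation and overlap diagnostics.

The observed data are a single rectangular table holding, for every row,
an outcome ``Y``, a binary treatment ``A``, a binary source indicator
``S`` (1 = randomized trial, 0 = observational study), and a covariate
matrix ``X`` of which an ordered subset ``X*`` feeds the prediction model
under evaluation.  The container enforces the complete-case contract (no
missing values anywhere) and preserves row order end-to-end so estimator
terms can be audited row-wise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CompletenessError,
    DomainError,
    EstimabilityError,
    SchemaError,
    StateError,
)

__all__ = [
    "MultiSourceDataset",
    "OverlapReport",
    "load_dataset",
    "read_schema",
    "validate_cells",
    "positivity_diagnostics",
]

ANALYSES = ("observational", "transportability", "joint")


@dataclass
class MultiSourceDataset:
    """Validated multi-source data (Y, A, S, X, X* designation).

    Attributes
    ----------
    y, a, s : ndarray
        Outcome, treatment indicator (0/1) and source indicator
        (1 = trial, 0 = observational), one entry per row.
    x : DataFrame
        Numeric covariate matrix with named columns (categoricals already
        one-hot encoded).
    xstar_columns : list of str
        Ordered designation of the model covariates X* ⊆ X.
    """

    y: np.ndarray
    a: np.ndarray
    s: np.ndarray
    x: pd.DataFrame
    xstar_columns: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.a = np.asarray(self.a)
        self.s = np.asarray(self.s)
        if not isinstance(self.x, pd.DataFrame):
            self.x = pd.DataFrame(np.asarray(self.x, dtype=float))
            self.x.columns = [str(c) for c in self.x.columns]
        n = len(self.y)
        if not (len(self.a) == len(self.s) == len(self.x) == n):
            raise SchemaError("Y, A, S and X must have the same number of rows")
        for name, vec in (("A", self.a), ("S", self.s)):
            vals = set(np.unique(vec).tolist())
            if not vals <= {0, 1}:
                raise DomainError(f"{name} must be binary 0/1; found values {sorted(vals)}")
        self.a = self.a.astype(int)
        self.s = self.s.astype(int)
        if not np.all(np.isfinite(self.y)):
            raise CompletenessError("missing or non-finite values in outcome Y")
        xvals = self.x.to_numpy(dtype=float)
        if not np.all(np.isfinite(xvals)):
            raise CompletenessError("missing or non-finite values in covariates X")
        self.xstar_columns = [str(c) for c in self.xstar_columns]
        missing = [c for c in self.xstar_columns if c not in self.x.columns]
        if missing:
            raise SchemaError(f"xstar columns not in X: {missing}")
        if self.n0 < 1 or self.n1 < 1:
            raise DomainError(
                f"both sources must be non-empty (n0={self.n0}, n1={self.n1})"
            )

    # -- bookkeeping ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n0(self) -> int:
        return int(np.sum(self.s == 0))

    @property
    def n1(self) -> int:
        return int(np.sum(self.s == 1))

    @property
    def xstar(self) -> pd.DataFrame:
        """The X* block of the covariate matrix, in designation order."""
        return self.x[self.xstar_columns]

    def take(self, idx) -> "MultiSourceDataset":
        """Row subset/reindex (used by the stratified bootstrap)."""
        idx = np.asarray(idx)
        return MultiSourceDataset(
            y=self.y[idx],
            a=self.a[idx],
            s=self.s[idx],
            x=self.x.iloc[idx].reset_index(drop=True),
            xstar_columns=list(self.xstar_columns),
        )


@dataclass
class OverlapReport:
    """Positivity/overlap diagnostics.

    Ranges of the estimated treatment propensities per source and of the
    estimated trial-participation probability over the target (S=0) rows,
    plus the indices of target rows whose participation probability falls
    below ``threshold``.  Advisory only — nothing aborts on a flag.
    """

    treatment_propensity_range_by_source: dict[int, tuple[float, float]]
    participation_prob_range_on_target: tuple[float, float]
    flagged_rows: list[int]
    threshold: float

    def to_json(self) -> str:
        payload = {
            "treatment_propensity_range_by_source": {
                str(k): list(v)
                for k, v in self.treatment_propensity_range_by_source.items()
            },
            "participation_prob_range_on_target": list(
                self.participation_prob_range_on_target
            ),
            "flagged_rows": [int(i) for i in self.flagged_rows],
            "threshold": self.threshold,
        }
        return json.dumps(payload, indent=2)


def read_schema(path) -> dict:
    """Read a schema/config mapping from a YAML or JSON file.

    Expected keys: ``outcome``, ``treatment``, ``source``, ``covariates``,
    ``xstar`` (optional), ``categoricals`` (optional).
    """
    import yaml

    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError(f"schema file {path} did not parse to a mapping")
    return schema


def _encode_categoricals(
    df: pd.DataFrame, covariates: list[str], categoricals: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode declared categoricals deterministically.

    Levels are ordered lexicographically (as strings) and the first level is
    dropped so design matrices stay full rank.  Returns the encoded matrix
    and a map from original name to encoded column names.
    """
    blocks: list[pd.DataFrame] = []
    name_map: dict[str, list[str]] = {}
    for col in covariates:
        if col in categoricals:
            levels = sorted(df[col].astype(str).unique())
            encoded_names = [f"{col}={lev}" for lev in levels[1:]]
            block = pd.DataFrame(
                {
                    name: (df[col].astype(str) == lev).astype(float).to_numpy()
                    for name, lev in zip(encoded_names, levels[1:])
                },
                index=df.index,
            )
            name_map[col] = encoded_names
            blocks.append(block)
        else:
            name_map[col] = [col]
            blocks.append(df[[col]].astype(float))
    encoded = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
    return encoded, name_map


def load_dataset(path, schema, xstar: list[str] | None = None) -> MultiSourceDataset:
    """Load a CSV table into a validated :class:`MultiSourceDataset`.

    Parameters
    ----------
    path
        CSV file (RFC-4180, header row required).
    schema
        Mapping (or path to a YAML/JSON file) with keys ``outcome``,
        ``treatment``, ``source``, ``covariates`` and optionally ``xstar``
        and ``categoricals``.
    xstar
        Overrides ``schema["xstar"]``; defaults to all covariates
        (X* = X) when neither is given.
    """
    if not isinstance(schema, dict):
        schema = read_schema(schema)
    for key in ("outcome", "treatment", "source", "covariates"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    df = pd.read_csv(path)
    covariates = list(schema["covariates"])
    categoricals = list(schema.get("categoricals", []))
    needed = [schema["outcome"], schema["treatment"], schema["source"], *covariates]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"columns missing from {path}: {missing}")
    sub = df[needed]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise CompletenessError(f"missing values in columns {bad} (complete-case contract)")

    x, name_map = _encode_categoricals(df, covariates, categoricals)
    if xstar is None:
        xstar = list(schema.get("xstar", covariates))
    xstar_encoded: list[str] = []
    for col in xstar:
        if col not in name_map:
            raise SchemaError(f"xstar column {col!r} is not a declared covariate")
        xstar_encoded.extend(name_map[col])

    return MultiSourceDataset(
        y=df[schema["outcome"]].to_numpy(dtype=float),
        a=df[schema["treatment"]].to_numpy(),
        s=df[schema["source"]].to_numpy(),
        x=x.reset_index(drop=True),
        xstar_columns=xstar_encoded,
    )


def validate_cells(ds: MultiSourceDataset, a: int, analysis: str) -> bool:
    """Confirm the conditioning cells required by an analysis are non-empty.

    observational needs (S=0, A=a); transportability needs (S=1, A=a) and
    S=0 rows; joint needs (A=a) anywhere and S=0 rows.  The observational
    check never inspects treatment data from S=1 rows.
    """
    if analysis not in ANALYSES:
        raise DomainError(f"analysis must be one of {ANALYSES}, got {analysis!r}")
    if analysis == "observational":
        a_target = ds.a[ds.s == 0]
        if not np.any(a_target == a):
            raise EstimabilityError(f"empty cell (S=0, A={a}) for observational analysis")
    elif analysis == "transportability":
        if not np.any((ds.s == 1) & (ds.a == a)):
            raise EstimabilityError(f"empty cell (S=1, A={a}) for transportability analysis")
    else:  # joint
        if not np.any(ds.a == a):
            raise EstimabilityError(f"no rows with A={a} for joint analysis")
    # all analyses average over the target sample; the container already
    # guarantees n0 >= 1
    return True


def positivity_diagnostics(ds: MultiSourceDataset, nuis, threshold: float = 0.01) -> OverlapReport:
    """Examine the testable positivity assumptions on the observed data.

    Reports the range of estimated treatment propensities Pr(A=1 | X, S=s)
    within each source for which a propensity model was fitted, the range
    of the estimated participation probability Pr(S=1 | X) over target
    (S=0) rows, and flags target rows with participation probability below
    ``threshold`` (near-violations of trial positivity).
    """
    from .nuisance import NuisanceSet  # local import to avoid a cycle

    if not isinstance(nuis, NuisanceSet):
        raise StateError("positivity_diagnostics requires a fitted NuisanceSet")
    if nuis.participation is None:
        raise StateError("participation model not fitted")
    prop_ranges: dict[int, tuple[float, float]] = {}
    for source, model in sorted(nuis.e.items()):
        mask = ds.s == source
        p = model.prob(ds.x[mask])
        prop_ranges[int(source)] = (float(np.min(p)), float(np.max(p)))
    target = ds.s == 0
    p_part = nuis.participation.prob(ds.x[target])
    target_idx = np.flatnonzero(target)
    flagged = target_idx[p_part < threshold]
    return OverlapReport(
        treatment_propensity_range_by_source=prop_ranges,
        participation_prob_range_on_target=(float(np.min(p_part)), float(np.max(p_part))),
        flagged_rows=[int(i) for i in flagged],
        threshold=threshold,
    )
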
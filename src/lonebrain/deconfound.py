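"""Nuisance-variable residualization and standardization.

Every feature block (region volumes, coupling edges, tract FA) is cleaned the
same way before modeling: the least-squares projection onto a confound design
matrix (intercept + z-scored continuous confounds + one-hot acquisition site)
is removed, then columns are z-scored across participants.  The order
(residualize first, z-score the residuals) is a package choice exposed by the
``standardize_first`` switch on :class:`ConfoundRegressor`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CohortTable

__all__ = [
    "ConfoundMatrix",
    "build_confound_matrix",
    "residualize",
    "standardize",
    "ConfoundRegressor",
    "clean_features",
    "DEFAULT_CONFOUNDS",
]

#: The standard nuisance set applied in all three analysis arms.
DEFAULT_CONFOUNDS = (
    "bmi",
    "head_size",
    "motion_task",
    "motion_rest",
    "head_pos_x",
    "head_pos_y",
    "head_pos_z",
    "table_pos",
    "site",
)


@dataclass
class ConfoundMatrix:
    """Full-column-rank design: intercept, z-scored continuous, one-hot site."""

    design: np.ndarray   # (n, q)
    names: list[str]

    @property
    def q(self) -> int:
        return self.design.shape[1]


def build_confound_matrix(
    cohort: CohortTable | pd.DataFrame,
    confound_names: list[str] | tuple[str, ...] = DEFAULT_CONFOUNDS,
    *,
    age_degree: int = 0,
) -> ConfoundMatrix:
    """Assemble the confound design from named phenotype columns.

    Continuous columns are centered and scaled; categorical (object/str)
    columns are one-hot encoded with the alphabetically first level dropped as
    reference; an intercept column is prepended.  ``age_degree > 0`` adds
    polynomial age columns (sensitivity analyses with higher-order age
    effects).  A rank-deficient design raises, naming collinear columns.
    """
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for name in confound_names:
        if name not in df.columns:
            raise KeyError(f"confound column {name!r} not in phenotype table")
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            for lev in levels[1:]:  # drop first level as reference
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        else:
            x = col.to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"confound column {name!r} is constant")
            cols.append((x - x.mean()) / sd)
            names.append(name)
    for d in range(2, age_degree + 1):
        a = df["age"].to_numpy(dtype=float)
        a = (a - a.mean()) / a.std(ddof=1)
        cols.append(a**d)
        names.append(f"age^{d}")

    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"confound design is rank-deficient; collinear columns: {bad}")
    return ConfoundMatrix(design=design, names=names)


def residualize(features: np.ndarray, confounds: ConfoundMatrix) -> np.ndarray:
    """Remove the least-squares projection of each column onto the design."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    C = confounds.design
    if X.shape[0] != C.shape[0]:
        raise ValueError("feature and confound row counts differ")
    if X.shape[0] <= C.shape[1]:
        raise ValueError(
            f"need more rows ({X.shape[0]}) than confound columns ({C.shape[1]})"
        )
    coef, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ coef


def standardize(features: np.ndarray) -> np.ndarray:
    """Column z-scores with the n-1 (sample) SD convention."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    sd = X.std(0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant feature column(s) at index {dead.tolist()}")
    return (X - X.mean(0)) / sd


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Transformer: residualize features on a confound design, then z-score.

    Parameters
    ----------
    standardize_output : bool, default True
        z-score residual columns (n-1 SD).  Edge features can skip the
        re-standardization after cleaning by setting this to False.
    standardize_first : bool, default False
        z-score features before residualization instead of after.
    """

    def __init__(self, standardize_output: bool = True, standardize_first: bool = False):
        self.standardize_output = standardize_output
        self.standardize_first = standardize_first

    def fit(self, X, y=None, *, confounds: ConfoundMatrix):
        X = np.asarray(X, dtype=float)
        if self.standardize_first:
            X = standardize(X)
        C = confounds.design
        if X.shape[0] <= C.shape[1]:
            raise ValueError("need n > q to fit the confound regression")
        self.confounds_ = confounds
        self.coef_, *_ = np.linalg.lstsq(C, X, rcond=None)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, confounds: ConfoundMatrix | None = None):
        conf = confounds if confounds is not None else self.confounds_
        X = np.asarray(X, dtype=float)
        if self.standardize_first:
            X = standardize(X)
        R = X - conf.design @ self.coef_
        if self.standardize_output:
            R = standardize(R)
        return R

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def clean_features(
    features: np.ndarray,
    cohort: CohortTable,
    confound_names=DEFAULT_CONFOUNDS,
    *,
    restandardize: bool = True,
) -> np.ndarray:
    """One-call cleaning: build design, residualize, optionally z-score."""
    cm = build_confound_matrix(cohort, confound_names)
    R = residualize(features, cm)
    return standardize(R) if restandardize else R
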
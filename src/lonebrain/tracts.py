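"""Tract-microstructure associations with the binary phenotype.

For each of the 48 tract mean-FA columns: Pearson correlation (the
point-biserial correlation, since the phenotype is binary) and Spearman rank
correlation with two-sided analytic p-values, Bonferroni family-wise
correction at m = 48 within each statistic family, 5-95% percentile bootstrap
intervals of the Pearson coefficient over participant resamples, and a
ranking by |Pearson rho| (descending, ties broken by catalog order).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .atlas import TractCatalog, load_tract_catalog

log = logging.getLogger("lonebrain")

__all__ = [
    "tract_associations",
    "bootstrap_cis",
    "adjust_bonferroni",
    "TractAssociation",
]


def _check_inputs(fa: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fa = np.asarray(fa, dtype=float)
    y = np.asarray(y, dtype=float)
    if fa.ndim != 2 or fa.shape[0] != y.size:
        raise ValueError("fa must be (n, T) with rows matching y")
    if np.unique(y).size < 2:
        raise ValueError("phenotype y is constant; need both classes")
    dead = np.flatnonzero(fa.std(0) == 0)
    if dead.size:
        raise ValueError(f"constant FA column(s) at index {dead.tolist()}")
    return fa, y


def adjust_bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """Family-wise correction: min(1, m * p) elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def tract_associations(
    fa: np.ndarray, y: np.ndarray, catalog: TractCatalog | None = None
) -> pd.DataFrame:
    """Per-tract Pearson and Spearman coefficients, raw and Bonferroni p-values,
    and |Pearson|-descending rank (catalog order breaks ties)."""
    fa, y = _check_inputs(fa, y)
    catalog = catalog if catalog is not None else load_tract_catalog()
    T = fa.shape[1]
    if T != catalog.n_tracts:
        raise ValueError(f"fa has {T} columns, catalog lists {catalog.n_tracts} tracts")
    pearson = np.empty(T)
    p_pearson = np.empty(T)
    spearman = np.empty(T)
    p_spearman = np.empty(T)
    for t in range(T):
        r = stats.pearsonr(fa[:, t], y)
        pearson[t], p_pearson[t] = r.statistic, r.pvalue
        s = stats.spearmanr(fa[:, t], y)
        spearman[t], p_spearman[t] = s.statistic, s.pvalue
    # |rho| descending; stable sort keeps catalog order on ties
    order = np.argsort(-np.abs(pearson), kind="stable")
    rank = np.empty(T, dtype=int)
    rank[order] = np.arange(1, T + 1)
    return pd.DataFrame(
        {
            "tract": list(catalog.tracts),
            "pearson_rho": pearson,
            "spearman_rho": spearman,
            "p_raw": p_pearson,
            "p_bonferroni": adjust_bonferroni(p_pearson, T),
            "p_spearman_raw": p_spearman,
            "p_spearman_bonferroni": adjust_bonferroni(p_spearman, T),
            "rank": rank,
        }
    )


def bootstrap_cis(
    fa: np.ndarray,
    y: np.ndarray,
    B: int = 100,
    seed: int = 0,
    *,
    max_retries: int = 100,
) -> pd.DataFrame:
    """5-95% percentile bootstrap intervals of the per-tract Pearson rho.

    Participants are resampled with replacement B times; a resample that loses
    one phenotype class is redrawn (logged), up to ``max_retries`` per
    iteration.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    fa, y = _check_inputs(fa, y)
    n, T = fa.shape
    rng = np.random.default_rng(seed)
    est = np.empty((B, T))
    redraws = 0
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        fb = fa[idx]
        # vectorized Pearson across columns
        fb_c = fb - fb.mean(0)
        yb_c = yb - yb.mean()
        denom = np.sqrt((fb_c**2).sum(0) * (yb_c**2).sum())
        est[b] = (fb_c.T @ yb_c) / denom
    if redraws:
        log.info("bootstrap: redrew %d single-class resamples", redraws)
    lo = np.percentile(est, 5, axis=0)
    hi = np.percentile(est, 95, axis=0)
    return pd.DataFrame({"ci5": lo, "ci95": hi})


class TractAssociation(BaseEstimator):
    """sklearn-style front end: fit produces the full association table.

    ``table_`` columns: tract, pearson_rho, spearman_rho, ci5, ci95, p_raw,
    p_bonferroni (and the Spearman-family p-values), rank.
    """

    def __init__(self, n_bootstrap: int = 100, seed: int = 0):
        self.n_bootstrap = n_bootstrap
        self.seed = seed

    def fit(self, X, y, *, catalog: TractCatalog | None = None):
        catalog = catalog if catalog is not None else load_tract_catalog()
        table = tract_associations(X, y, catalog)
        cis = bootstrap_cis(X, y, B=self.n_bootstrap, seed=self.seed)
        table.insert(3, "ci5", cis["ci5"])
        table.insert(4, "ci95", cis["ci95"])
        self.table_ = table
        self.top_tracts_ = tuple(
            table.sort_values("rank")["tract"].head(3)
        )
        return self
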
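"""Dominant PLS population mode linking coupling edges to the binary phenotype.

The variable set X holds the 4950 lower-triangle functional-coupling edges
(standardized and deconfounded upstream); the target encodes the phenotype as
+1/-1.  With a univariate target the first PLS component's x-weights are
exactly the normalized X-by-y cross-covariance, which is how they are computed
here; the participant scores are the projection of centered X onto those
weights and the mode statistic is the Pearson correlation between scores and
labels (sign convention: non-negative).  Statistical robustness is assessed by
a label-permutation null that refits the full mode per shuffle; edge weights
are back-projected to 7x7 network-block means for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator

from .atlas import Atlas

__all__ = [
    "EdgeVector",
    "PLSMode",
    "PermutationResult",
    "vectorize_connectome",
    "devectorize_edges",
    "fit_pls_mode",
    "permutation_test",
    "network_block_summary",
    "PLSPhenotypeMode",
]


@dataclass
class EdgeVector:
    """Lower-triangle edge values with their (i > j) row-major index pairs."""

    values: np.ndarray
    edge_index: list[tuple[int, int]]


@dataclass
class PLSMode:
    """First PLS component: unit-norm edge weights, scores, mode correlation."""

    x_weights: np.ndarray   # (E,), unit L2 norm
    scores: np.ndarray      # (n,)
    mode_corr: float        # Pearson rho between scores and labels, >= 0
    k: int = 1


@dataclass
class PermutationResult:
    observed: float
    null_stats: np.ndarray
    p_value: float
    B: int
    seed: int


def edge_index_pairs(R: int) -> list[tuple[int, int]]:
    ii, jj = np.tril_indices(R, k=-1)
    return list(zip(ii.tolist(), jj.tolist()))


def vectorize_connectome(M: np.ndarray) -> EdgeVector:
    """Row-major lower triangle (i > j) of a symmetric coupling matrix."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("connectome must be symmetric to 1e-8")
    R = M.shape[0]
    ii, jj = np.tril_indices(R, k=-1)
    return EdgeVector(values=M[ii, jj].copy(), edge_index=edge_index_pairs(R))


def devectorize_edges(values: np.ndarray, R: int) -> np.ndarray:
    """Inverse of :func:`vectorize_connectome`: symmetric matrix, zero diagonal."""
    values = np.asarray(values, dtype=float)
    if values.size != R * (R - 1) // 2:
        raise ValueError(f"expected {R * (R - 1) // 2} edges for R={R}")
    M = np.zeros((R, R))
    ii, jj = np.tril_indices(R, k=-1)
    M[ii, jj] = values
    M[jj, ii] = values
    return M


def _as_pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    vals = np.unique(y)
    if vals.size < 2:
        raise ValueError("need both phenotype classes present")
    if set(vals) == {0.0, 1.0}:
        y = 2.0 * y - 1.0
    elif set(vals) != {-1.0, 1.0}:
        raise ValueError("labels must be binary (0/1 or -1/+1)")
    return y


def fit_pls_mode(X: np.ndarray, y: np.ndarray) -> PLSMode:
    """First-component PLS of edges against the +-1 phenotype.

    x_weights = normalize(Xc^T yc); scores = Xc @ x_weights; the weight sign
    is chosen so corr(scores, y) >= 0.
    """
    X = np.asarray(X, dtype=float)
    y = _as_pm1(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    Xc = X - X.mean(0)
    yc = y - y.mean()
    w = Xc.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("degenerate mode: zero cross-covariance between X and y")
    w /= nrm
    scores = Xc @ w
    rho = float(pearsonr(scores, y).statistic)
    if rho < 0:
        w, scores, rho = -w, -scores, -rho
    return PLSMode(x_weights=w, scores=scores, mode_corr=rho)


def permutation_test(
    X: np.ndarray, y: np.ndarray, B: int = 1000, seed: int = 0
) -> PermutationResult:
    """Label-shuffling null for the mode correlation, full refit per shuffle.

    One-sided in the positive orientation of the sign convention; add-one
    p-value (1 + #{null >= observed}) / (1 + B), never exactly zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _as_pm1(y)
    observed = fit_pls_mode(X, y).mode_corr
    rng = np.random.default_rng(seed)
    null_stats = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        null_stats[b] = fit_pls_mode(X, y_perm).mode_corr
    p = (1.0 + np.count_nonzero(null_stats >= observed)) / (1.0 + B)
    return PermutationResult(
        observed=observed, null_stats=null_stats, p_value=float(p), B=B, seed=seed
    )


def network_block_summary(mode: PLSMode, atlas: Atlas) -> np.ndarray:
    """Mean edge weight per network pair: symmetric (K, K) block matrix."""
    E = atlas.n_edges
    if mode.x_weights.size != E:
        raise ValueError(f"mode has {mode.x_weights.size} edges, atlas implies {E}")
    nets = np.asarray(atlas.region_to_network)
    ii, jj = np.tril_indices(atlas.n_regions, k=-1)
    a, b = nets[ii], nets[jj]
    K = atlas.n_networks
    sums = np.zeros((K, K))
    counts = np.zeros((K, K))
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    np.add.at(sums, (lo, hi), mode.x_weights)
    np.add.at(counts, (lo, hi), 1.0)
    with np.errstate(invalid="ignore"):
        block = sums / counts
    block = np.where(counts > 0, block, 0.0)
    return np.triu(block) + np.triu(block, 1).T


class PLSPhenotypeMode(BaseEstimator):
    """sklearn-style front end: fit the dominant mode, optionally test it.

    Fitted attributes: ``x_weights_`` (unit norm), ``scores_``, ``mode_corr_``,
    and after :meth:`permutation_test`, ``permutation_`` with the null
    distribution and add-one p-value.
    """

    def __init__(self, n_permutations: int = 1000, seed: int = 0):
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, X, y):
        mode = fit_pls_mode(X, y)
        self.mode_ = mode
        self.x_weights_ = mode.x_weights
        self.scores_ = mode.scores
        self.mode_corr_ = mode.mode_corr
        return self

    def transform(self, X):
        Xc = np.asarray(X, float) - np.asarray(X, float).mean(0)
        return Xc @ self.x_weights_

    def permutation_test(self, X, y) -> PermutationResult:
        self.permutation_ = permutation_test(
            X, y, B=self.n_permutations, seed=self.seed
        )
        return self.permutation_

    def network_blocks(self, atlas: Atlas) -> np.ndarray:
        return network_block_summary(self.mode_, atlas)
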
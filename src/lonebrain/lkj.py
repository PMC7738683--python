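"""LKJ-distributed correlation Cholesky factors via canonical partial correlations.

The within-network correlation structure of the region-level model uses the
C-vine parameterization of the LKJ distribution: a d x d correlation Cholesky
factor is built from d(d-1)/2 partial correlations w = tanh(y) with the
closed-form spherical row construction

    L[i, j] = w[i, j] * prod_{k<j} sqrt(1 - w[i, k]^2)      (j < i)
    L[i, i] = prod_{k<i} sqrt(1 - w[i, k]^2)

Under LKJ(eta), the canonical partial correlation in column j (0-based) is an
independent scaled Beta(b, b) variable on (-1, 1) with b = eta + (d - 2 - j)/2,
so the prior factorizes over entries and both the density and its gradient on
the unconstrained scale are elementwise.  For d = 2 this reduces to the known
Beta(eta, eta) marginal of the single correlation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln

__all__ = [
    "n_cpc",
    "cholesky_from_unconstrained",
    "grad_cholesky_backward",
    "lkj_cpc_logp_grad",
    "sample_lkj_cholesky",
]


def n_cpc(d: int) -> int:
    return d * (d - 1) // 2


def _rows(d: int):
    """Row-major (i, j) pairs, i > j, matching the flat parameter layout."""
    for i in range(1, d):
        for j in range(i):
            yield i, j


def cholesky_from_unconstrained(y: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Build L (lower, unit-diagonal-norm rows) from unconstrained y; returns (L, w)."""
    if y.size != n_cpc(d):
        raise ValueError(f"expected {n_cpc(d)} entries for d={d}, got {y.size}")
    w = np.tanh(y)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, d):
        wi = w[pos : pos + i]
        pos += i
        c = np.sqrt(1.0 - wi**2)
        P = np.concatenate(([1.0], np.cumprod(c)))  # P[j] = prod_{k<j} c_k
        L[i, :i] = wi * P[:i]
        L[i, i] = P[i]
    return L, w


def grad_cholesky_backward(
    G: np.ndarray, L: np.ndarray, w: np.ndarray, d: int
) -> np.ndarray:
    """Backpropagate dl/dL (lower triangular incl. diagonal) to dl/dy.

    Uses dL[i,j]/dw_m = -w_m / (1 - w_m^2) * L[i,j] for m < j <= i and
    dL[i,m]/dw_m = P_m, combined with dw/dy = 1 - w^2.
    """
    g_y = np.zeros_like(w)
    pos = 0
    for i in range(1, d):
        wi = w[pos : pos + i]
        c2 = 1.0 - wi**2
        P = np.concatenate(([1.0], np.cumprod(np.sqrt(c2))))
        GL = G[i, : i + 1] * L[i, : i + 1]          # j = 0..i
        # suffix sums S_m = sum_{j>m} G[i,j] L[i,j]
        S = np.cumsum(GL[::-1])[::-1]
        S_next = np.concatenate((S[1:], [0.0]))[:i]  # S over j=m+1..i
        g_y[pos : pos + i] = G[i, :i] * P[:i] * c2 - wi * S_next
        pos += i
    return g_y


def lkj_cpc_logp_grad(y: np.ndarray, d: int, eta: float) -> tuple[float, np.ndarray]:
    """Independent scaled-Beta prior on the CPCs, on the unconstrained scale.

    Includes the tanh Jacobian; per entry the log density in y is
    b * log(1 - w^2) + const with b = eta + (d - 2 - j)/2.
    """
    w = np.tanh(y)
    b = np.empty_like(y)
    pos = 0
    for i in range(1, d):
        b[pos : pos + i] = eta + (d - 2 - np.arange(i)) / 2.0
        pos += i
    const = -(np.log(2.0) * (2.0 * b - 1.0) + betaln(b, b)).sum()
    logp = float((b * np.log1p(-(w**2))).sum() + const)
    return logp, -2.0 * b * w


def sample_lkj_cholesky(d: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation Cholesky factor ~ LKJ(eta) via the vine method."""
    y = np.empty(n_cpc(d))
    pos = 0
    for i in range(1, d):
        b = eta + (d - 2 - np.arange(i)) / 2.0
        w = 2.0 * rng.beta(b, b) - 1.0
        y[pos : pos + i] = np.arctanh(w)
        pos += i
    L, _ = cholesky_from_unconstrained(y, d)
    return L
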
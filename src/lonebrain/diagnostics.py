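"""Posterior summaries: highest-density intervals and split-Rhat convergence."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["hpd_interval", "compute_rhat"]


def hpd_interval(
    samples: np.ndarray, lower: float = 0.05, upper: float = 0.95
) -> tuple[float, float]:
    """Narrowest interval containing the central ``upper - lower`` posterior mass.

    The 5-95% convention corresponds to the 90% highest-density interval; for
    symmetric unimodal posteriors it coincides with the 5th-95th percentile
    interval.  Computed by scanning all contiguous windows of the sorted
    sample that hold the requested mass.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    mass = upper - lower
    if not 0 < mass <= 1:
        raise ValueError("need 0 < upper - lower <= 1")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def compute_rhat(draws: np.ndarray) -> float:
    """Classic split-Rhat (potential scale reduction) for one parameter.

    ``draws`` has shape (chains, samples); each chain is split in half, and
    Rhat = sqrt(((n-1)/n * W + B/n) / W) over the 2*chains half-chains.
    Constant chains are reported as 1.0 with a warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws of shape (chains >= 2, samples)")
    c, s = draws.shape
    if s < 4:
        raise ValueError("need at least 4 samples per chain for split-Rhat")
    half = s // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    if np.allclose(split.var(axis=1, ddof=1), 0) and np.allclose(
        split.mean(axis=1), split.mean()
    ):
        warnings.warn("constant chains; Rhat defined as 1.0", RuntimeWarning)
        return 1.0
    n = half
    chain_means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        warnings.warn("zero within-chain variance; Rhat defined as inf", RuntimeWarning)
        return float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
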
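"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained gradient-based MCMC engine used by the hierarchical volume
models.  The target is supplied as a callable returning the joint log density
and its gradient on the unconstrained scale.  The implementation follows the
standard recursive tree-doubling scheme with a slice variable, a divergence
threshold of 1000 on the energy error, dual averaging toward a target
acceptance statistic (0.8 by default), and a warmup schedule of fast
(step-size-only) windows bracketing doubling slow windows in which the
diagonal metric is estimated from the warmup draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["nuts_sample", "NUTSStats"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DELTA_MAX = 1000.0


@dataclass
class NUTSStats:
    """Per-draw sampler statistics for one chain."""

    accept_stat: np.ndarray
    tree_depth: np.ndarray
    n_divergent: int
    step_size: float
    inv_mass: np.ndarray
    energy: np.ndarray = field(default=None)


class _Welford:
    """Streaming mean/variance for metric adaptation."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit metric (Stan's shrinkage)
        w = self.n / (self.n + 5.0)
        return w * var + 1e-3 * (1 - w)


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    g: np.ndarray,
    eps: float,
    inv_mass: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    p1 = p + 0.5 * eps * g
    x1 = x + eps * inv_mass * p1
    lp1, g1 = logp_grad(x1)
    p1 = p1 + 0.5 * eps * g1
    return x1, p1, lp1, g1


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(p @ (inv_mass * p))


def _find_reasonable_epsilon(
    logp_grad: LogpGrad,
    x: np.ndarray,
    inv_mass: np.ndarray,
    rng: np.random.Generator,
) -> float:
    eps = 1.0
    lp, g = logp_grad(x)
    p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, x, p, g, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**a
        _, p1, lp1, _ = _leapfrog(logp_grad, x, p, g, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= -a * np.log(2.0):
            break
    return eps


class _Tree:
    """Recursive NUTS tree builder (one transition)."""

    def __init__(
        self,
        logp_grad: LogpGrad,
        eps: float,
        inv_mass: np.ndarray,
        log_u: float,
        h0: float,
        rng: np.random.Generator,
    ):
        self.logp_grad = logp_grad
        self.eps = eps
        self.inv_mass = inv_mass
        self.log_u = log_u
        self.h0 = h0
        self.rng = rng
        self.sum_accept = 0.0
        self.n_steps = 0
        self.divergent = False

    def build(self, x, p, g, direction, depth):
        if depth == 0:
            x1, p1, lp1, g1 = _leapfrog(
                self.logp_grad, x, p, g, direction * self.eps, self.inv_mass
            )
            h1 = lp1 - _kinetic(p1, self.inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n_valid = int(self.log_u <= h1)
            stop = self.log_u - _DELTA_MAX > h1
            if stop:
                self.divergent = True
            self.sum_accept += min(1.0, np.exp(h1 - self.h0))
            self.n_steps += 1
            return x1, p1, g1, x1, p1, g1, x1, g1, lp1, n_valid, stop
        # left subtree
        (xm, pm, gm, xp, pp, gp, xs, gs, lps, n1, stop) = self.build(
            x, p, g, direction, depth - 1
        )
        if stop:
            return xm, pm, gm, xp, pp, gp, xs, gs, lps, n1, True
        # right subtree continues from the outermost state in `direction`
        if direction == -1:
            (xm, pm, gm, _, _, _, xs2, gs2, lps2, n2, stop2) = self.build(
                xm, pm, gm, direction, depth - 1
            )
        else:
            (_, _, _, xp, pp, gp, xs2, gs2, lps2, n2, stop2) = self.build(
                xp, pp, gp, direction, depth - 1
            )
        if n1 + n2 > 0 and self.rng.random() < n2 / (n1 + n2):
            xs, gs, lps = xs2, gs2, lps2
        dx = xp - xm
        uturn = (dx @ (self.inv_mass * pm) < 0) or (dx @ (self.inv_mass * pp) < 0)
        return xm, pm, gm, xp, pp, gp, xs, gs, lps, n1 + n2, stop2 or uturn


def nuts_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    *,
    n_tune: int = 1000,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, NUTSStats]:
    """Run one chain; returns draws of shape (n_draws, dim) and statistics."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.array(x0, dtype=float)
    dim = x.size
    inv_mass = np.ones(dim)
    lp, g = logp_grad(x)
    if not np.isfinite(lp):
        raise RuntimeError("sampler initialization failure: non-finite log density at x0")

    # warmup schedule: fast(15%) | doubling slow windows | fast(10%)
    init_fast = max(1, int(0.15 * n_tune))
    term_fast = max(1, int(0.10 * n_tune))
    slow_total = max(0, n_tune - init_fast - term_fast)
    slow_ends: list[int] = []
    w, pos = 25, init_fast
    while slow_total > 0 and pos < init_fast + slow_total:
        w_eff = min(w, init_fast + slow_total - pos)
        # absorb a too-small trailing window into the last one
        if (init_fast + slow_total - (pos + w_eff)) < 25 and (pos + w_eff) < init_fast + slow_total:
            w_eff = init_fast + slow_total - pos
        pos += w_eff
        slow_ends.append(pos)
        w *= 2

    eps = _find_reasonable_epsilon(logp_grad, x, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    welford = _Welford(dim)
    draws = np.empty((n_draws, dim))
    accept_stats = np.empty(n_tune + n_draws)
    depths = np.empty(n_tune + n_draws, dtype=int)
    energies = np.empty(n_draws)
    n_div = 0

    for it in range(n_tune + n_draws):
        tuning = it < n_tune
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(p0, inv_mass)
        log_u = h0 + np.log(rng.random())
        tree = _Tree(logp_grad, eps, inv_mass, log_u, h0, rng)
        xm, pm, gm = x, p0, g
        xp, pp, gp = x, p0, g
        n_valid, depth, stop = 1, 0, False
        while not stop and depth < max_treedepth:
            direction = -1 if rng.random() < 0.5 else 1
            if direction == -1:
                (xm, pm, gm, _, _, _, xs, gs, lps, n2, stop2) = tree.build(
                    xm, pm, gm, direction, depth
                )
            else:
                (_, _, _, xp, pp, gp, xs, gs, lps, n2, stop2) = tree.build(
                    xp, pp, gp, direction, depth
                )
            if not stop2 and n2 > 0 and rng.random() < min(1.0, n2 / n_valid):
                x, g, lp = xs, gs, lps
            n_valid += n2
            dx = xp - xm
            uturn = (dx @ (inv_mass * pm) < 0) or (dx @ (inv_mass * pp) < 0)
            stop = stop2 or uturn
            depth += 1

        if tree.divergent and not tuning:
            n_div += 1
        accept_prob = tree.sum_accept / max(tree.n_steps, 1)
        accept_stats[it] = accept_prob
        depths[it] = depth

        if tuning:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            in_slow = slow_ends and init_fast <= it and it < slow_ends[-1]
            if in_slow:
                welford.update(x)
            if slow_ends and (it + 1) in slow_ends:
                inv_mass = welford.variance()
                welford = _Welford(dim)
                eps = _find_reasonable_epsilon(logp_grad, x, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == n_tune - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_tune] = x
            energies[it - n_tune] = -lp

    stats = NUTSStats(
        accept_stat=accept_stats[n_tune:],
        tree_depth=depths[n_tune:],
        n_divergent=n_div,
        step_size=eps,
        inv_mass=inv_mass.copy(),
        energy=energies,
    )
    return draws, stats
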
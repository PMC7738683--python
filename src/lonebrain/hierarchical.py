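"""Bayesian hierarchical logistic models of loneliness on regional volumes.

Two model kinds link the binary outcome to the 100 z-scored regional
gray-matter volumes through the atlas's region -> network hierarchy:

* ``region_level`` - each network's coefficient block gets its own
  per-region scales (half-normal priors) and, by default, within-network
  correlations under an LKJ(eta) prior; ``diagonal=True`` drops the
  correlations.
* ``network_level`` - all regions of a network share one variance component
  sigma_network (half-normal prior, diagonal covariance), so the posterior of
  sigma ranks networks by how much coefficient variance they carry.

Both include sex-specific intercepts and sex-specific slopes on z-scored age
(standard-normal priors), mirroring the nuisance terms of the displayed model.
The sampler is the package's own NUTS implementation; region coefficients use
a non-centered parameterization (beta = sigma * z) for well-behaved geometry
under weak signal.  Stratified fits duplicate the coefficient blocks per sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .atlas import Atlas, load_atlas
from .diagnostics import compute_rhat, hpd_interval
from .lkj import (
    cholesky_from_unconstrained,
    grad_cholesky_backward,
    lkj_cpc_logp_grad,
    n_cpc,
)
from .sampler import nuts_sample

log = logging.getLogger("lonebrain")

__all__ = [
    "ModelData",
    "ModelSpec",
    "PosteriorDraws",
    "PosteriorSummary",
    "build_model",
    "fit",
    "summarize",
    "threshold_regions",
    "HierarchicalVolumeModel",
]

ALPHA_NAMES = ("alpha_men", "alpha_women", "alpha_men_age", "alpha_women_age")


@dataclass
class ModelData:
    """Design for the volume arm: z-scored volumes, outcome, sex, z-scored age."""

    X: np.ndarray        # (n, R), columns mean 0 / sd 1
    y: np.ndarray        # (n,), binary
    sex: np.ndarray      # (n,), 1 = man
    age_z: np.ndarray    # (n,)
    atlas: Atlas
    groups: np.ndarray | None = None  # optional per-row group index

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, r = self.X.shape
        if r != self.atlas.n_regions:
            raise ValueError(
                f"X has {r} columns but atlas defines {self.atlas.n_regions} regions"
            )
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        mu = np.abs(self.X.mean(0)).max()
        sd = np.abs(self.X.std(0, ddof=1) - 1).max()
        if mu > 1e-6 or sd > 1e-6:
            raise ValueError(
                "X columns must be z-scored (mean 0, sample sd 1 to 1e-6); "
                "run the deconfounding/standardization step first"
            )


@dataclass
class ModelSpec:
    """Prior and structure configuration."""

    kind: Literal["region_level", "network_level"] = "network_level"
    sigma_scale: float = 1.0       # half-normal scale for sigma / region scales
    lkj_eta: float = 2.0
    diagonal: bool = False         # region_level only: drop LKJ correlations
    grouping: Literal["pooled", "by_sex"] = "pooled"


class _LogPosterior:
    """Packed unconstrained parameterization with analytic gradient."""

    def __init__(self, data: ModelData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        atlas = data.atlas
        self.R = atlas.n_regions
        self.K = atlas.n_networks
        self.net_of = np.asarray(atlas.region_to_network)
        self.blocks = [np.asarray(atlas.regions_in_network(k)) for k in range(self.K)]
        self.block_dims = [len(b) for b in self.blocks]

        if spec.grouping == "by_sex":
            self.group_of = data.sex.astype(int)  # 0 = women, 1 = men
            self.G = 2
            self.group_names = ("women", "men")
        else:
            self.group_of = np.zeros(len(data.y), dtype=int)
            self.G = 1
            self.group_names = ("all",)
        self.group_rows = [np.flatnonzero(self.group_of == g) for g in range(self.G)]

        sex, age_z = data.sex, data.age_z
        self.A = np.column_stack(
            [sex, 1 - sex, sex * age_z, (1 - sex) * age_z]
        ).astype(float)

        if spec.kind == "network_level":
            self.per_group = self.R + self.K
        else:
            self.n_lkj = 0 if spec.diagonal else sum(n_cpc(d) for d in self.block_dims)
            self.per_group = 2 * self.R + self.n_lkj
        self.dim = self.G * self.per_group + 4

    # --- packing ------------------------------------------------------------
    def _split_group(self, theta: np.ndarray, g: int) -> np.ndarray:
        return theta[g * self.per_group : (g + 1) * self.per_group]

    def _alphas(self, theta: np.ndarray) -> np.ndarray:
        return theta[-4:]

    def betas(self, theta: np.ndarray) -> np.ndarray:
        """Constrained region coefficients, shape (G, R)."""
        out = np.empty((self.G, self.R))
        for g in range(self.G):
            out[g] = self._group_beta(self._split_group(theta, g))[0]
        return out

    def scales(self, theta: np.ndarray) -> np.ndarray:
        """sigma per network (network_level, (G, K)) or per region ((G, R))."""
        cols = self.K if self.spec.kind == "network_level" else self.R
        out = np.empty((self.G, cols))
        for g in range(self.G):
            t = self._split_group(theta, g)
            if self.spec.kind == "network_level":
                out[g] = np.exp(t[self.R : self.R + self.K])
            else:
                out[g] = np.exp(t[self.R : 2 * self.R])
        return out

    def _group_beta(self, t: np.ndarray):
        """Return (beta, cache) for one group's packed block."""
        spec = self.spec
        z = t[: self.R]
        if spec.kind == "network_level":
            u = t[self.R : self.R + self.K]
            sigma = np.exp(u)
            beta = sigma[self.net_of] * z
            return beta, (z, u, sigma)
        v = t[self.R : 2 * self.R]
        tau = np.exp(v)
        beta = np.empty(self.R)
        cache = []
        pos = 2 * self.R
        for k, idx in enumerate(self.blocks):
            d = self.block_dims[k]
            zk = z[idx]
            if spec.diagonal or d == 1:
                a = zk
                Lwy = None
            else:
                yk = t[pos : pos + n_cpc(d)]
                pos += n_cpc(d)
                L, w = cholesky_from_unconstrained(yk, d)
                a = L @ zk
                Lwy = (L, w, yk)
            beta[idx] = tau[idx] * a
            cache.append((a, Lwy))
        return beta, (z, v, tau, cache)

    # --- joint log density ----------------------------------------------------
    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        data, spec = self.data, self.spec
        X, y = data.X, data.y
        alpha = self._alphas(theta)
        grad = np.zeros_like(theta)

        eta = self.A @ alpha
        group_caches = []
        for g in range(self.G):
            t = self._split_group(theta, g)
            beta, cache = self._group_beta(t)
            rows = self.group_rows[g]
            eta[rows] += X[rows] @ beta
            group_caches.append((beta, cache))

        # Bernoulli-logit likelihood
        logp = float(y @ eta - np.logaddexp(0.0, eta).sum())
        resid = y - _expit(eta)

        # nuisance terms: N(0,1) priors
        grad[-4:] = self.A.T @ resid - alpha
        logp += float(-0.5 * alpha @ alpha)

        s2 = spec.sigma_scale**2
        for g in range(self.G):
            t = self._split_group(theta, g)
            beta, cache = group_caches[g]
            rows = self.group_rows[g]
            g_beta = X[rows].T @ resid[rows]
            gt = np.zeros(self.per_group)
            if spec.kind == "network_level":
                z, u, sigma = cache
                gt[: self.R] = g_beta * sigma[self.net_of] - z
                g_u = np.zeros(self.K)
                np.add.at(g_u, self.net_of, g_beta * beta)
                gt[self.R :] = g_u - sigma**2 / s2 + 1.0
                logp += float(-0.5 * z @ z - 0.5 * (sigma**2).sum() / s2 + u.sum())
            else:
                z, v, tau, bcache = cache
                g_z = np.zeros(self.R)
                pos = 2 * self.R
                for k, idx in enumerate(self.blocks):
                    d = self.block_dims[k]
                    a, Lwy = bcache[k]
                    tg = tau[idx] * g_beta[idx]
                    if Lwy is None:
                        g_z[idx] = tg
                    else:
                        L, w, yk = Lwy
                        g_z[idx] = L.T @ tg
                        G_L = np.tril(np.outer(tg, z[idx]))
                        g_y = grad_cholesky_backward(G_L, L, w, d)
                        lp_lkj, g_lkj = lkj_cpc_logp_grad(yk, d, spec.lkj_eta)
                        gt[pos : pos + n_cpc(d)] = g_y + g_lkj
                        logp += lp_lkj
                        pos += n_cpc(d)
                gt[: self.R] = g_z - z
                gt[self.R : 2 * self.R] = g_beta * beta - tau**2 / s2 + 1.0
                logp += float(-0.5 * z @ z - 0.5 * (tau**2).sum() / s2 + v.sum())
            grad[g * self.per_group : (g + 1) * self.per_group] = gt
        return logp, grad


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class PosteriorDraws:
    """Constrained posterior draws: (chains, samples, ...) arrays."""

    beta: np.ndarray                 # (C, S, G, R)
    scale: np.ndarray                # (C, S, G, K) or (C, S, G, R)
    alpha: np.ndarray                # (C, S, 4)
    spec: ModelSpec
    atlas: Atlas
    group_names: tuple[str, ...]
    sampler_stats: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]


@dataclass
class PosteriorSummary:
    """Tabular posterior summary plus the network importance ranking."""

    table: pd.DataFrame              # parameter, group, mean, hpd5, hpd95, rhat, flagged
    network_ranking: tuple[str, ...]
    network_sigma_mean: dict[str, float]

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


def build_model(data: ModelData, spec: ModelSpec) -> _LogPosterior:
    """Assemble the packed log-posterior for the requested model kind."""
    return _LogPosterior(data, spec)


def fit(
    model: _LogPosterior,
    chains: int = 4,
    tune: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    *,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> PosteriorDraws:
    """Sample the posterior with NUTS; chains run sequentially with spawned seeds."""
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if tune < 1 or draws < 1:
        raise ValueError("tune and draws must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    C, S = chains, draws
    G, R = model.G, model.R
    scale_cols = model.K if model.spec.kind == "network_level" else R
    beta_d = np.empty((C, S, G, R))
    scale_d = np.empty((C, S, G, scale_cols))
    alpha_d = np.empty((C, S, 4))
    stats = []
    for c in range(C):
        rng = np.random.default_rng(child[c])
        x0 = 0.1 * rng.standard_normal(model.dim)
        raw, st = nuts_sample(
            model,
            x0,
            n_tune=tune,
            n_draws=draws,
            seed=rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        for s in range(S):
            beta_d[c, s] = model.betas(raw[s])
            scale_d[c, s] = model.scales(raw[s])
            alpha_d[c, s] = raw[s][-4:]
        stats.append(st)
        log.info(
            "chain %d/%d: step_size=%.3g divergences=%d mean_depth=%.1f",
            c + 1, C, st.step_size, st.n_divergent, st.tree_depth.mean(),
        )
    return PosteriorDraws(
        beta=beta_d,
        scale=scale_d,
        alpha=alpha_d,
        spec=model.spec,
        atlas=model.data.atlas,
        group_names=model.group_names,
        sampler_stats=stats,
    )


def summarize(
    draws: PosteriorDraws, lower: float = 0.05, upper: float = 0.95
) -> PosteriorSummary:
    """Posterior mean, 5-95% HPD bounds and split-Rhat for every parameter,
    plus networks ranked by the posterior mean of their variance component
    (descending; ties broken by canonical network order)."""
    atlas = draws.atlas
    rows = []

    def add(name: str, group: str, chain_draws: np.ndarray, flag: bool = False):
        flat = chain_draws.reshape(-1)
        lo, hi = hpd_interval(flat, lower, upper)
        rhat = compute_rhat(chain_draws)
        flagged = ""
        if flag:
            flagged = "+" if lo > 0 else ("-" if hi < 0 else "")
        rows.append(
            {
                "parameter": name,
                "group": group,
                "mean": float(flat.mean()),
                "hpd5": lo,
                "hpd95": hi,
                "rhat": rhat,
                "flagged": flagged,
            }
        )

    for g, gname in enumerate(draws.group_names):
        for r in range(atlas.n_regions):
            add(
                f"beta_region[{atlas.regions[r].name}]",
                gname,
                draws.beta[:, :, g, r],
                flag=True,
            )
        if draws.spec.kind == "network_level":
            for k, net in enumerate(atlas.networks):
                add(f"sigma_network[{net}]", gname, draws.scale[:, :, g, k])
        else:
            for r in range(atlas.n_regions):
                add(
                    f"scale_region[{atlas.regions[r].name}]",
                    gname,
                    draws.scale[:, :, g, r],
                )
    for a, aname in enumerate(ALPHA_NAMES):
        add(aname, "all", draws.alpha[:, :, a])

    # network ranking from the pooled (first) group
    if draws.spec.kind == "network_level":
        net_means = draws.scale[:, :, 0, :].reshape(-1, draws.scale.shape[-1]).mean(0)
    else:
        net_of = np.asarray(atlas.region_to_network)
        per_region = draws.scale[:, :, 0, :].reshape(-1, atlas.n_regions)
        rms = np.sqrt((per_region**2).mean(0))
        net_means = np.array(
            [rms[net_of == k].mean() for k in range(atlas.n_networks)]
        )
    order = sorted(
        range(atlas.n_networks), key=lambda k: (-net_means[k], k)
    )
    ranking = tuple(atlas.networks[k] for k in order)
    sigma_mean = {atlas.networks[k]: float(net_means[k]) for k in range(atlas.n_networks)}
    return PosteriorSummary(
        table=pd.DataFrame(rows), network_ranking=ranking, network_sigma_mean=sigma_mean
    )


def threshold_regions(summary: PosteriorSummary) -> pd.DataFrame:
    """Regions whose 5-95% HPD excludes zero, with association sign."""
    t = summary.table
    mask = t["parameter"].str.startswith("beta_region") & (t["flagged"] != "")
    return t.loc[mask, ["parameter", "group", "mean", "hpd5", "hpd95", "flagged"]].reset_index(
        drop=True
    )


class HierarchicalVolumeModel(BaseEstimator):
    """sklearn-style front end for the hierarchical volume models.

    Parameters mirror :class:`ModelSpec` plus sampler settings.  ``fit`` takes
    the z-scored volume matrix and the binary outcome, with ``sex`` and ``age``
    as fit parameters; fitted attributes are ``draws_``, ``summary_``,
    ``network_ranking_`` and ``max_rhat_``.  ``paper_settings=True`` selects
    the long warmup preset (tune=4000, draws=1000).
    """

    def __init__(
        self,
        kind: str = "network_level",
        stratify_sex: bool = False,
        sigma_scale: float = 1.0,
        lkj_eta: float = 2.0,
        diagonal: bool = False,
        chains: int = 4,
        tune: int = 1000,
        draws: int = 1000,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
        paper_settings: bool = False,
        seed: int = 0,
    ):
        self.kind = kind
        self.stratify_sex = stratify_sex
        self.sigma_scale = sigma_scale
        self.lkj_eta = lkj_eta
        self.diagonal = diagonal
        self.chains = chains
        self.tune = tune
        self.draws = draws
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.paper_settings = paper_settings
        self.seed = seed

    def fit(self, X, y, *, sex, age, atlas: Atlas | None = None):
        atlas = atlas if atlas is not None else load_atlas()
        age = np.asarray(age, dtype=float)
        age_z = (age - age.mean()) / age.std(ddof=1)
        data = ModelData(
            X=np.asarray(X, dtype=float),
            y=np.asarray(y),
            sex=np.asarray(sex, dtype=int),
            age_z=age_z,
            atlas=atlas,
        )
        spec = ModelSpec(
            kind=self.kind,
            sigma_scale=self.sigma_scale,
            lkj_eta=self.lkj_eta,
            diagonal=self.diagonal,
            grouping="by_sex" if self.stratify_sex else "pooled",
        )
        tune = 4000 if self.paper_settings else self.tune
        draws = 1000 if self.paper_settings else self.draws
        self.model_ = build_model(data, spec)
        self.draws_ = fit(
            self.model_,
            chains=self.chains,
            tune=tune,
            draws=draws,
            seed=self.seed,
            target_accept=self.target_accept,
            max_treedepth=self.max_treedepth,
        )
        self.summary_ = summarize(self.draws_)
        self.network_ranking_ = self.summary_.network_ranking
        self.max_rhat_ = self.summary_.max_rhat
        return self

    def predict_proba(self, X, *, sex, age):
        """Posterior-mean probability of the outcome for new rows."""
        beta = self.draws_.beta[:, :, 0, :].reshape(-1, self.model_.R).mean(0)
        alpha = self.draws_.alpha.reshape(-1, 4).mean(0)
        sex = np.asarray(sex, dtype=int)
        age = np.asarray(age, dtype=float)
        age_z = (age - age.mean()) / age.std(ddof=1)
        A = np.column_stack([sex, 1 - sex, sex * age_z, (1 - sex) * age_z])
        p = _expit(np.asarray(X, float) @ beta + A @ alpha)
        return np.column_stack([1 - p, p])
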
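"""Two-isotope Bayesian stable-isotope mixing model (SIMM).

Estimates the proportional contribution ``p`` of K candidate sources to a
consumer's tissue from carbon and nitrogen isotope values, in the standard
process-error formulation: consumer observation i on isotope j is

    x_ij ~ Normal( sum_k p_k (mu_kj + lambda_j),
                   sum_k p_k^2 (sigma_kj^2 + tau_j^2) [+ eps_j^2] )

where (mu_kj, sigma_kj) are the source summaries, (lambda_j, tau_j) the
trophic discrimination factor mean and SD for isotope j, and eps_j an
optional residual-error scale. The prior on p is Dirichlet(alpha).

Sampling works on the isometric log-ratio (ILR) transform of the simplex
with the shared adaptive Metropolis-within-Gibbs sampler; a deterministic
grid-integration oracle is provided for problems with at most three sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.special import gammaln

from ._samplers import MCMCSettings, ess_bulk, sample_posterior, split_rhat
from .isotope_prep import SourceSummary
from .trophic_position import TDFSpec

DEFAULT_TDF_C = TDFSpec(0.0, 1.0)   # no established carbon TDF: neutral default
DEFAULT_TDF_N = TDFSpec(3.15, 1.28)


@dataclass
class MixingModelSpec:
    sources: Sequence[SourceSummary]
    consumer_obs: np.ndarray            # (n, 2) columns d13C, d15N
    tdf_C: TDFSpec = DEFAULT_TDF_C
    tdf_N: TDFSpec = DEFAULT_TDF_N
    dirichlet_alpha: Optional[Sequence[float]] = None  # default all ones
    residual_error: bool = False
    sd_floor: Optional[float] = None    # required for sources with missing SD

    def __post_init__(self) -> None:
        self.consumer_obs = np.atleast_2d(np.asarray(self.consumer_obs, float))
        if len(self.sources) < 1:
            raise ValueError("need at least one source")
        if self.consumer_obs.shape[0] < 1 or self.consumer_obs.shape[1] != 2:
            raise ValueError("consumer_obs must be (n, 2)")
        if self.dirichlet_alpha is not None:
            a = np.asarray(self.dirichlet_alpha, float)
            if len(a) != len(self.sources) or np.any(a <= 0):
                raise ValueError("dirichlet_alpha must be positive, one per source")


def ilr_basis(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) basis of the clr hyperplane."""
    return helmert(k).T


def ilr_inverse(z: np.ndarray, basis: np.ndarray) -> np.ndarray:
    y = basis @ z
    y -= y.max()
    e = np.exp(y)
    return e / e.sum()


def ilr(p: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return basis.T @ np.log(p)


class MixingModel:
    """Bound data + log-density evaluators, built once per problem."""

    def __init__(self, spec: MixingModelSpec):
        self.spec = spec
        self.source_names = [s.taxon for s in spec.sources]
        self.k = len(spec.sources)
        mu = np.empty((self.k, 2))
        var = np.empty((self.k, 2))
        for i, s in enumerate(spec.sources):
            sds = (s.sd_d13C, s.sd_d15N)
            if any(sd is None for sd in sds):
                if spec.sd_floor is None:
                    raise ValueError(
                        f"source '{s.taxon}' has a missing SD and no sd_floor is set")
                sds = tuple(spec.sd_floor if sd is None else sd for sd in sds)
            mu[i] = (s.mean_d13C + spec.tdf_C.mean, s.mean_d15N + spec.tdf_N.mean)
            var[i] = (sds[0] ** 2 + spec.tdf_C.sd ** 2,
                      sds[1] ** 2 + spec.tdf_N.sd ** 2)
        self.mu = mu          # TDF-shifted source means, (K, 2)
        self.var = var        # source + TDF variance, (K, 2)
        x = spec.consumer_obs
        self.n_obs = x.shape[0]
        self.sx = x.sum(axis=0)
        self.sx2 = (x ** 2).sum(axis=0)
        self.alpha = (np.ones(self.k) if spec.dirichlet_alpha is None
                      else np.asarray(spec.dirichlet_alpha, float))
        self.basis = ilr_basis(self.k) if self.k > 1 else None
        self._ln_dir_const = (gammaln(self.alpha.sum())
                              - gammaln(self.alpha).sum())

    # -- densities ---------------------------------------------------------

    def loglik(self, p: np.ndarray, resid2: np.ndarray | float = 0.0) -> float:
        m = p @ self.mu                       # mixture mean per isotope
        v = (p ** 2) @ self.var + resid2      # mixture variance per isotope
        n = self.n_obs
        ll = (-0.5 * n * np.log(2 * np.pi * v)
              - (self.sx2 - 2 * m * self.sx + n * m ** 2) / (2 * v))
        return float(ll.sum())

    def log_density_p(self, p: np.ndarray, resid2: np.ndarray | float = 0.0) -> float:
        """Fully-normalized prior x likelihood density on the open simplex."""
        p = np.asarray(p, float)
        if np.any(p <= 0) or abs(p.sum() - 1) > 1e-9:
            return -np.inf
        log_prior = self._ln_dir_const + float(((self.alpha - 1) * np.log(p)).sum())
        return log_prior + self.loglik(p, resid2)

    def log_post_z(self, theta: np.ndarray) -> float:
        """Log target in ILR coordinates (+ optional log residual scales)."""
        z = theta[: self.k - 1]
        if self.spec.residual_error:
            le = theta[self.k - 1:]
            resid2 = np.exp(2 * le)
            # half-normal(5) prior on eps + Jacobian of the log transform
            extra = float((-0.5 * (np.exp(le) / 5.0) ** 2 + le).sum())
        else:
            resid2, extra = 0.0, 0.0
        p = ilr_inverse(z, self.basis)
        if np.any(p < 1e-300):
            return -np.inf
        # + sum(log p): Jacobian of the ILR -> simplex transform
        return self.log_density_p(p, resid2) + float(np.log(p).sum()) + extra


def build_mixing_model(spec: MixingModelSpec) -> MixingModel:
    return MixingModel(spec)


@dataclass
class MixingPosterior:
    source_names: list[str]
    draws: np.ndarray                  # (chains, kept, K), rows on the simplex
    mean: np.ndarray                   # (K,)
    sd: np.ndarray
    quantiles: pd.DataFrame            # index: quantile level, columns: sources
    rhat: np.ndarray                   # per source component
    ess: np.ndarray
    converged: bool
    seed: int
    warning: Optional[str] = None

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


_QLEVELS = (0.025, 0.25, 0.50, 0.75, 0.975)


def _posterior_from_draws(model: MixingModel, draws: np.ndarray,
                          converged: bool, seed: int) -> MixingPosterior:
    flat = draws.reshape(-1, model.k)
    q = pd.DataFrame(np.percentile(flat, [100 * x for x in _QLEVELS], axis=0),
                     index=list(_QLEVELS), columns=model.source_names)
    return MixingPosterior(
        source_names=list(model.source_names), draws=draws,
        mean=flat.mean(axis=0), sd=flat.std(axis=0, ddof=1), quantiles=q,
        rhat=split_rhat(draws) if draws.shape[0] >= 2 else np.full(model.k, np.nan),
        ess=ess_bulk(draws), converged=converged, seed=seed,
        warning=None if converged else
        "chains did not converge (split-Rhat >= 1.05); increase iterations")


def fit_mixing(model: MixingModel,
               mcmc: MCMCSettings = MCMCSettings()) -> MixingPosterior:
    """MCMC over the ILR-transformed contribution vector."""
    if model.k == 1:
        kept = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
        draws = np.ones((mcmc.chains, kept, 1))
        return _posterior_from_draws(model, draws, True, mcmc.seed)
    n_par = model.k - 1 + (2 if model.spec.residual_error else 0)

    def init(rng: np.random.Generator) -> np.ndarray:
        x = rng.normal(0, 0.3, n_par)
        if model.spec.residual_error:
            x[model.k - 1:] = np.log(0.5) + rng.normal(0, 0.1, 2)
        return x

    res = sample_posterior(model.log_post_z, init, n_par, mcmc)
    z = res.draws[:, :, : model.k - 1]
    chains, kept = z.shape[0], z.shape[1]
    p = np.empty((chains, kept, model.k))
    for ci in range(chains):
        for t in range(kept):
            p[ci, t] = ilr_inverse(z[ci, t], model.basis)
    return _posterior_from_draws(model, p, res.converged, mcmc.seed)


def grid_oracle(model: MixingModel, resolution: float = 0.002) -> np.ndarray:
    """Posterior mean contributions by deterministic numeric integration.

    Supports at most three sources (simplex grids beyond that are
    intractable); ``resolution`` is the grid step in contribution units.
    Residual-error models are not integrable on the p-grid alone.
    """
    if model.k > 3:
        raise ValueError("grid oracle supports at most 3 sources")
    if model.spec.residual_error:
        raise ValueError("grid oracle does not support residual-error models")
    if model.k == 1:
        return np.array([1.0])
    if model.k == 2:
        p1 = np.arange(resolution / 2, 1.0, resolution)
        logd = np.array([model.log_density_p(np.array([a, 1 - a])) for a in p1])
        w = np.exp(logd - logd.max())
        w /= w.sum()
        m1 = float((w * p1).sum())
        return np.array([m1, 1 - m1])
    # K = 3: midpoint rule on the 2-simplex lattice
    h = max(resolution, 0.004)
    grid = np.arange(h / 2, 1.0, h)
    pts = [(a, b) for a in grid for b in grid if a + b < 1.0]
    logd = np.array([model.log_density_p(np.array([a, b, 1 - a - b]))
                     for a, b in pts])
    w = np.exp(logd - logd.max())
    w /= w.sum()
    arr = np.asarray(pts)
    m1 = float((w * arr[:, 0]).sum())
    m2 = float((w * arr[:, 1]).sum())
    return np.array([m1, m2, 1 - m1 - m2])


def summarize_contributions(post: MixingPosterior) -> pd.DataFrame:
    """Percentage-scale summary table, ordered by posterior mean descending."""
    rows = []
    for i, name in enumerate(post.source_names):
        rows.append({
            "source": name,
            "mean_pct": 100 * post.mean[i],
            "sd_pct": 100 * post.sd[i],
            **{f"q{int(1000 * q) / 10:g}_pct": 100 * post.quantiles.loc[q].iloc[i]
               for q in _QLEVELS},
            "rhat": post.rhat[i],
        })
    df = pd.DataFrame(rows).sort_values("mean_pct", ascending=False,
                                        kind="mergesort").reset_index(drop=True)
    return df
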
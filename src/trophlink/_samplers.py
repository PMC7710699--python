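"""Adaptive random-walk Metropolis-within-Gibbs sampler with diagnostics.

One shared sampler backs both Bayesian modules. Each scalar parameter gets
its own Gaussian proposal whose log-scale is tuned toward a 0.44 acceptance
rate by per-iteration Robbins-Monro updates during burn-in only;
post-burn-in transitions are plain Metropolis, so the retained chain
targets the exact posterior. Chains are seeded from a single
``SeedSequence`` so runs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    iterations: int = 10_000  # total per chain, including burn-in
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.chains < 1 or self.thin < 1:
            raise ValueError("chains and thin must be >= 1")


@dataclass
class SamplerResult:
    draws: np.ndarray           # (chains, kept, n_params)
    accept_rate: np.ndarray     # (chains, n_params)
    rhat: np.ndarray            # (n_params,)
    ess: np.ndarray             # (n_params,)
    converged: bool
    seed: int


def _run_chain(logpost: Callable[[np.ndarray], float], x0: np.ndarray,
               settings: MCMCSettings, rng: np.random.Generator,
               lower: np.ndarray, upper: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(x0)
    x = x0.copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial point")
    log_step = np.zeros(n)
    kept = (settings.iterations - settings.burn_in) // settings.thin
    out = np.empty((kept, n))
    acc = np.zeros(n)
    k = 0
    for t in range(settings.iterations):
        adapting = t < settings.burn_in
        gamma = min(0.25, 5.0 / (t + 20.0)) if adapting else 0.0
        for j in range(n):
            prop = x[j] + np.exp(log_step[j]) * rng.standard_normal()
            accepted = False
            if lower[j] <= prop <= upper[j]:
                x_prop = x.copy()
                x_prop[j] = prop
                lp_prop = logpost(x_prop)
                if np.log(rng.uniform()) < lp_prop - lp:
                    x = x_prop
                    lp = lp_prop
                    accepted = True
                    if not adapting:
                        acc[j] += 1
            if adapting:  # Robbins-Monro toward a 0.44 acceptance rate
                log_step[j] += gamma * ((1.0 if accepted else 0.0) - 0.44)
        if not adapting and (t - settings.burn_in) % settings.thin == 0:
            out[k] = x
            k += 1
    n_kept = settings.iterations - settings.burn_in
    return out[:k], acc / max(n_kept, 1)


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per parameter."""
    c, m, p = draws.shape
    half = m // 2
    halves = np.concatenate([draws[:, :half, :], draws[:, half:2 * half, :]], axis=0)
    cc, mm, _ = halves.shape
    chain_mean = halves.mean(axis=1)                     # (2c, p)
    chain_var = halves.var(axis=1, ddof=1)               # (2c, p)
    b = mm * chain_mean.var(axis=0, ddof=1)
    w = chain_var.mean(axis=0)
    var_plus = (mm - 1) / mm * w + b / mm
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / w)
    return np.where(w <= 1e-300, 1.0, r)


def ess_bulk(draws: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter (Geyer initial monotone sequence)."""
    c, m, p = draws.shape
    out = np.empty(p)
    for j in range(p):
        x = draws[:, :, j]
        if np.allclose(x, x.flat[0]):
            out[j] = c * m
            continue
        # pooled autocorrelation averaged over chains
        xc = x - x.mean(axis=1, keepdims=True)
        var = (xc ** 2).mean()
        if var <= 1e-300:
            out[j] = c * m
            continue
        max_lag = min(m - 1, 1000)
        rho = np.empty(max_lag)
        for lag in range(1, max_lag + 1):
            rho[lag - 1] = (xc[:, :-lag] * xc[:, lag:]).mean() / var
        # Geyer: sum pairs while positive
        tau = 1.0
        for k in range(0, max_lag - 1, 2):
            pair = rho[k] + rho[k + 1]
            if pair < 0:
                break
            tau += 2 * pair
        out[j] = c * m / tau
    return out


def sample_posterior(logpost: Callable[[np.ndarray], float],
                     init: Callable[[np.random.Generator], np.ndarray],
                     n_params: int,
                     settings: MCMCSettings,
                     lower: Optional[Sequence[float]] = None,
                     upper: Optional[Sequence[float]] = None,
                     rhat_threshold: float = 1.05) -> SamplerResult:
    """Run independent adaptive chains and report split-Rhat/ESS.

    Non-convergence (any Rhat above the threshold) never raises: the result
    carries ``converged=False`` and callers surface the flag.
    """
    lo = np.full(n_params, -np.inf) if lower is None else np.asarray(lower, float)
    hi = np.full(n_params, np.inf) if upper is None else np.asarray(upper, float)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    all_draws = []
    all_acc = []
    for c in range(settings.chains):
        rng = np.random.default_rng(seeds[c])
        draws, acc = _run_chain(logpost, init(rng), settings, rng, lo, hi)
        all_draws.append(draws)
        all_acc.append(acc)
    draws = np.stack(all_draws)          # (chains, kept, n_params)
    rhat = split_rhat(draws) if settings.chains >= 2 else np.full(n_params, np.nan)
    ess = ess_bulk(draws)
    converged = bool(settings.chains < 2 or np.all(rhat < rhat_threshold))
    return SamplerResult(draws=draws, accept_rate=np.stack(all_acc),
                         rhat=rhat, ess=ess, converged=converged,
                         seed=settings.seed)
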
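"""Seeded validation experiments for the Bayesian modules.

These are the package's own calibration studies: oracle-equivalence checks
for the mixing model, simulation-based parameter recovery for both the
mixing model and the trophic-position model, and the closed-form degenerate
limit of the TP sampler. They are used by the test suite and by the
acceptance script; every experiment takes an explicit seed and returns
plain dataclass results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._samplers import MCMCSettings
from .isotope_prep import SourceSummary
from .mixing_model import MixingModelSpec, build_mixing_model, fit_mixing, grid_oracle
from .trophic_position import TDFSpec, TPModelSpec, fit_tp

# Field-style source summaries (myctophid vs euphausiid prey and a second
# myctophid) used across the recovery studies.
D_FRAGILIS = SourceSummary(taxon="Diaphus fragilis", n=11, mean_d13C=-18.2,
                           sd_d13C=0.3, mean_d15N=10.2, sd_d15N=0.5)
S_RUFINUS = SourceSummary(taxon="Symbolophorus rufinus", n=6, mean_d13C=-19.3,
                          sd_d13C=0.2, mean_d15N=9.3, sd_d15N=0.5)
E_GIBBOIDES = SourceSummary(taxon="Euphausia gibboides", n=6, mean_d13C=-19.3,
                            sd_d13C=1.0, mean_d15N=6.9, sd_d15N=0.2)
D_BRACHYCEPHALUS = SourceSummary(taxon="Diaphus brachycephalus", n=10,
                                 mean_d13C=-18.9, sd_d13C=0.3,
                                 mean_d15N=9.9, sd_d15N=0.8)

TDF_C = TDFSpec(0.0, 1.0)
TDF_N = TDFSpec(3.15, 1.28)


def _simulate_consumers(sources, p, n_obs, rng,
                        tdf_c=TDF_C, tdf_n=TDF_N) -> np.ndarray:
    lam = np.array([tdf_c.mean, tdf_n.mean])
    tau2 = np.array([tdf_c.sd, tdf_n.sd]) ** 2
    mu = np.array([[s.mean_d13C, s.mean_d15N] for s in sources]) + lam
    var = np.array([[s.sd_d13C ** 2, s.sd_d15N ** 2] for s in sources]) + tau2
    p = np.asarray(p, float)
    return rng.normal(p @ mu, np.sqrt((p ** 2) @ var), size=(n_obs, 2))


@dataclass
class OracleGapResult:
    max_abs_gap: float
    gaps: list[float]


def mixing_oracle_equivalence(seed: int,
                              mcmc: MCMCSettings | None = None) -> OracleGapResult:
    """MCMC vs grid-integration posterior means on 2-source problems.

    Three problems spanning balanced, skewed, and low-n consumer data; the
    returned gap is the largest |MCMC mean - grid mean| over problems and
    components.
    """
    rng = np.random.default_rng(seed)
    problems = [
        (([0.7, 0.3]), 20, (D_BRACHYCEPHALUS, E_GIBBOIDES)),
        (([0.5, 0.5]), 35, (D_FRAGILIS, E_GIBBOIDES)),
        (([0.15, 0.85]), 10, (S_RUFINUS, E_GIBBOIDES)),
    ]
    gaps = []
    for i, (p_true, n_obs, sources) in enumerate(problems):
        obs = _simulate_consumers(sources, p_true, n_obs, rng)
        model = build_mixing_model(MixingModelSpec(
            sources=list(sources), consumer_obs=obs))
        oracle = grid_oracle(model)
        settings = mcmc if mcmc is not None else MCMCSettings(seed=seed + 100 + i)
        if mcmc is not None:
            settings = MCMCSettings(chains=mcmc.chains, iterations=mcmc.iterations,
                                    burn_in=mcmc.burn_in, thin=mcmc.thin,
                                    seed=seed + 100 + i)
        post = fit_mixing(model, settings)
        gaps.append(float(np.abs(post.mean - oracle).max()))
    return OracleGapResult(max_abs_gap=max(gaps), gaps=gaps)


@dataclass
class MixingRecoveryResult:
    p_true: np.ndarray
    mean_posterior_mean: np.ndarray   # across replicates
    max_abs_bias: float               # |avg posterior mean - p_true|, worst comp.
    coverage: np.ndarray              # component-wise 95% CI coverage
    min_coverage: float
    n_replicates: int


def mixing_recovery(seed: int, n_replicates: int = 30, n_obs: int = 50,
                    p_true=(0.6, 0.3, 0.1),
                    mcmc_iterations: int = 5000) -> MixingRecoveryResult:
    """Simulate consumers from known contributions and refit per replicate."""
    sources = [D_FRAGILIS, S_RUFINUS, E_GIBBOIDES]
    p_true = np.asarray(p_true, float)
    cover = np.zeros(len(sources))
    means = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + 10_000 + r)
        obs = _simulate_consumers(sources, p_true, n_obs, rng)
        model = build_mixing_model(MixingModelSpec(
            sources=sources, consumer_obs=obs))
        post = fit_mixing(model, MCMCSettings(
            chains=2, iterations=mcmc_iterations,
            burn_in=mcmc_iterations // 2, seed=seed + 20_000 + r))
        means.append(post.mean)
        for k in range(len(sources)):
            lo = post.quantiles.loc[0.025].iloc[k]
            hi = post.quantiles.loc[0.975].iloc[k]
            cover[k] += lo <= p_true[k] <= hi
    mean_post = np.mean(means, axis=0)
    coverage = cover / n_replicates
    return MixingRecoveryResult(
        p_true=p_true, mean_posterior_mean=mean_post,
        max_abs_bias=float(np.abs(mean_post - p_true).max()),
        coverage=coverage, min_coverage=float(coverage.min()),
        n_replicates=n_replicates)


@dataclass
class TPClosedFormResult:
    max_z: float
    z_scores: list[float]


def tp_closed_form_limit(seed: int, n_triples: int = 3) -> TPClosedFormResult:
    """Degenerate-limit check: zero TDF sd and constant observations.

    For random (baseline, consumer, TDF) triples the posterior mean must sit
    within a few Monte-Carlo standard errors of (c - b)/TDF + 2.
    """
    rng = np.random.default_rng(seed)
    zs = []
    for i in range(n_triples):
        b = float(rng.uniform(-2, 4))
        tdf = float(rng.uniform(1.5, 4.0))
        tp_true = float(rng.uniform(2.5, 6.0))
        c = b + (tp_true - 2.0) * tdf
        spec = TPModelSpec(consumer_d15N=[c] * 5, baseline_d15N=[b] * 5,
                           tdf=TDFSpec(tdf, 0.0))
        post = fit_tp(spec, MCMCSettings(chains=2, iterations=4000,
                                         burn_in=2000, seed=seed + 300 + i))
        exact = (c - b) / tdf + 2.0
        mc_se = post.sd / np.sqrt(max(post.ess, 1.0))
        zs.append(float(abs(post.mean - exact) / max(mc_se, 1e-12)))
    return TPClosedFormResult(max_z=max(zs), z_scores=zs)


@dataclass
class TPRecoveryResult:
    true_tp: float
    coverage: float
    mean_posterior_mean: float
    n_replicates: int


def tp_recovery(seed: int, n_replicates: int = 50, true_tp: float = 4.2,
                n_obs: int = 30) -> TPRecoveryResult:
    """TP parameter recovery with the full uncertain-TDF prior."""
    hits = 0
    means = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + 40_000 + r)
        base = rng.normal(3.0, 0.6, n_obs)
        cons = rng.normal(3.0 + (true_tp - 2.0) * TDF_N.mean, 0.6, n_obs)
        post = fit_tp(TPModelSpec(consumer_d15N=cons, baseline_d15N=base,
                                  tdf=TDF_N),
                      MCMCSettings(chains=2, iterations=3000, burn_in=1500,
                                   seed=seed + 50_000 + r))
        hits += post.ci95[0] <= true_tp <= post.ci95[1]
        means.append(post.mean)
    return TPRecoveryResult(true_tp=true_tp, coverage=hits / n_replicates,
                            mean_posterior_mean=float(np.mean(means)),
                            n_replicates=n_replicates)
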
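import numpy as np
import pytest
from scipy import stats

from trophlink._samplers import MCMCSettings
from trophlink.isotope_prep import SourceSummary
from trophlink.mixing_model import (
    MixingModelSpec,
    build_mixing_model,
    fit_mixing,
    grid_oracle,
    ilr,
    ilr_basis,
    ilr_inverse,
    summarize_contributions,
)
from trophlink.trophic_position import TDFSpec

FAST = MCMCSettings(chains=2, iterations=5000, burn_in=2500, seed=21)


def src(name, d13c, s13, d15n, s15, n=8):
    return SourceSummary(taxon=name, n=n, mean_d13C=d13c, sd_d13C=s13,
                         mean_d15N=d15n, sd_d15N=s15)


MYCTOPHID = src("Diaphus brachycephalus", -18.9, 0.3, 9.9, 0.8, n=10)
EUPHAUSIID = src("Euphausia gibboides", -19.3, 1.0, 6.9, 0.2, n=6)


def two_source_spec(rng, n_obs=20):
    lam = np.array([0.0, 3.15])
    tau = np.array([1.0, 1.28])
    p = np.array([0.7, 0.3])
    mu = np.array([[-18.9, 9.9], [-19.3, 6.9]]) + lam
    var = np.array([[0.09, 0.64], [1.0, 0.04]]) + tau ** 2
    obs = rng.normal(p @ mu, np.sqrt((p ** 2) @ var), size=(n_obs, 2))
    return MixingModelSpec(sources=[MYCTOPHID, EUPHAUSIID], consumer_obs=obs)


class TestModelDensity:
    def test_single_source_posterior_is_unit(self):
        model = build_mixing_model(MixingModelSpec(
            sources=[MYCTOPHID], consumer_obs=[[-18.5, 12.0]]))
        post = fit_mixing(model, FAST)
        assert np.all(post.draws == 1.0)
        assert post.mean[0] == 1.0

    def test_symmetric_two_source_density(self):
        """Sources mirrored about the TDF-shifted consumer mean: p <-> 1-p."""
        tdf0 = TDFSpec(0.0, 0.5)
        spec = MixingModelSpec(
            sources=[src("A", -19.0, 0.4, 8.0, 0.4), src("B", -17.0, 0.4, 12.0, 0.4)],
            consumer_obs=[[-18.0, 10.0]], tdf_C=tdf0, tdf_N=tdf0)
        model = build_mixing_model(spec)
        for a in (0.1, 0.25, 0.4):
            assert model.log_density_p(np.array([a, 1 - a])) == pytest.approx(
                model.log_density_p(np.array([1 - a, a])), abs=1e-9)

    def test_density_matches_hand_coded_formula(self, rng):
        """Double-implementation check on random simplex points."""
        spec = two_source_spec(rng)
        model = build_mixing_model(spec)
        lam = np.array([0.0, 3.15])
        tau2 = np.array([1.0, 1.28]) ** 2
        mu_s = np.array([[-18.9, 9.9], [-19.3, 6.9]]) + lam
        var_s = np.array([[0.09, 0.64], [1.0, 0.04]]) + tau2
        x = spec.consumer_obs
        for _ in range(10):
            p1 = rng.uniform(0.05, 0.95)
            p = np.array([p1, 1 - p1])
            m = p @ mu_s
            v = (p ** 2) @ var_s
            want = stats.dirichlet.logpdf(p, [1.0, 1.0])
            want += stats.norm.logpdf(x, m, np.sqrt(v)).sum()
            assert model.log_density_p(p) == pytest.approx(float(want), rel=1e-10)

    def test_missing_sd_requires_floor(self):
        bad = SourceSummary(taxon="solo", n=1, mean_d13C=-19.0, mean_d15N=8.0)
        with pytest.raises(ValueError, match="sd_floor"):
            build_mixing_model(MixingModelSpec(
                sources=[bad, MYCTOPHID], consumer_obs=[[-18.0, 10.0]]))
        model = build_mixing_model(MixingModelSpec(
            sources=[bad, MYCTOPHID], consumer_obs=[[-18.0, 10.0]], sd_floor=0.2))
        assert model.var[0, 0] == pytest.approx(0.2 ** 2 + 1.0)

    def test_ilr_round_trip(self, rng):
        for k in (2, 3, 5, 9):
            basis = ilr_basis(k)
            p = rng.dirichlet(np.ones(k))
            np.testing.assert_allclose(ilr_inverse(ilr(p, basis), basis), p,
                                       atol=1e-12)


class TestFit:
    def test_symmetric_two_source_recovers_half(self):
        tdf0 = TDFSpec(0.0, 0.5)
        spec = MixingModelSpec(
            sources=[src("A", -19.0, 0.4, 8.0, 0.4), src("B", -17.0, 0.4, 12.0, 0.4)],
            consumer_obs=[[-18.0, 10.0]], tdf_C=tdf0, tdf_N=tdf0)
        post = fit_mixing(build_mixing_model(spec), FAST)
        assert post.mean[0] == pytest.approx(0.5, abs=0.05)

    def test_simplex_conservation_every_draw(self, rng):
        post = fit_mixing(build_mixing_model(two_source_spec(rng)), FAST)
        sums = post.draws.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert np.all(post.draws >= 0)

    def test_same_seed_identical_draws(self, rng):
        spec = two_source_spec(rng)
        a = fit_mixing(build_mixing_model(spec), FAST)
        b = fit_mixing(build_mixing_model(spec), FAST)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_label_equivariance(self, rng):
        """Permuting source order permutes the posterior summaries."""
        spec = two_source_spec(rng)
        fwd = fit_mixing(build_mixing_model(spec), FAST)
        swapped = MixingModelSpec(sources=list(spec.sources)[::-1],
                                  consumer_obs=spec.consumer_obs)
        rev = fit_mixing(build_mixing_model(swapped), FAST)
        assert fwd.mean[0] == pytest.approx(rev.mean[1], abs=0.02)
        assert fwd.mean[1] == pytest.approx(rev.mean[0], abs=0.02)

    def test_data_dominance_with_growing_n(self):
        """Consumers drawn from one TDF-shifted source pull its p toward 1."""
        lam = np.array([0.0, 3.15])
        tau2 = np.array([1.0, 1.28]) ** 2
        mu1 = np.array([-18.9, 9.9]) + lam
        v1 = np.array([0.09, 0.64]) + tau2
        rng = np.random.default_rng(8)
        means = []
        for n in (5, 20, 80):
            obs = rng.normal(mu1, np.sqrt(v1), size=(n, 2))
            spec = MixingModelSpec(sources=[MYCTOPHID, EUPHAUSIID],
                                   consumer_obs=obs)
            post = fit_mixing(build_mixing_model(spec),
                              MCMCSettings(chains=2, iterations=4000,
                                           burn_in=2000, seed=30 + n))
            means.append(post.mean[0])
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.9


class TestOracle:
    def test_single_source(self):
        model = build_mixing_model(MixingModelSpec(
            sources=[MYCTOPHID], consumer_obs=[[-18.5, 12.0]]))
        np.testing.assert_allclose(grid_oracle(model), [1.0])

    def test_mcmc_matches_oracle_two_sources(self, rng):
        model = build_mixing_model(two_source_spec(rng))
        oracle = grid_oracle(model)
        post = fit_mixing(model, FAST)
        assert np.abs(post.mean - oracle).max() < 0.02

    def test_oracle_resolution_convergence(self, rng):
        model = build_mixing_model(two_source_spec(rng))
        coarse = grid_oracle(model, resolution=0.004)
        fine = grid_oracle(model, resolution=0.002)
        assert np.abs(coarse - fine).max() < 1e-3

    def test_too_many_sources_unsupported(self, rng):
        spec = MixingModelSpec(
            sources=[MYCTOPHID, EUPHAUSIID,
                     src("C", -18.2, 0.3, 10.2, 0.5), src("D", -19.3, 0.2, 9.3, 0.5)],
            consumer_obs=[[-18.0, 10.0]])
        with pytest.raises(ValueError):
            grid_oracle(build_mixing_model(spec))


class TestSummary:
    def test_prior_predictive_uniform_means(self):
        """With no informative data, Dirichlet(1,..) means stay near 1/K."""
        sources = [src(c, -30.0 + 10 * i, 8.0, 5.0 + 2 * i, 8.0)
                   for i, c in enumerate("ABCD")]
        # one extremely vague observation: likelihood nearly flat in p
        spec = MixingModelSpec(sources=sources, consumer_obs=[[-15.0, 11.0]],
                               tdf_C=TDFSpec(0, 8.0), tdf_N=TDFSpec(0, 8.0))
        post = fit_mixing(build_mixing_model(spec),
                          MCMCSettings(chains=2, iterations=8000, burn_in=4000,
                                       seed=55))
        table = summarize_contributions(post)
        assert table["mean_pct"].sum() == pytest.approx(100, abs=0.1)
        np.testing.assert_allclose(post.mean, 0.25, atol=0.06)

    def test_summary_scale_order_and_nesting(self, rng):
        post = fit_mixing(build_mixing_model(two_source_spec(rng)), FAST)
        table = summarize_contributions(post)
        assert table["mean_pct"].is_monotonic_decreasing
        assert table["mean_pct"].sum() == pytest.approx(100, abs=0.1)
        for _, row in table.iterrows():
            assert row["q2.5_pct"] <= row["q25_pct"] <= row["q50_pct"] \
                <= row["q75_pct"] <= row["q97.5_pct"]
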
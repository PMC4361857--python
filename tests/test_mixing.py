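"""Mixing-model likelihood, MCMC, and posterior summary machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from isodiet import (DiscriminationFactor, MixingModelConfig, MixingProblem,
                     SourceGroup, fit_mixing_model, hdr, hdr_overlap_letters,
                     log_posterior, posterior_mode)

from .conftest import make_source_group


def one_channel_group(name, mu, omega=0.0, q=0.5):
    return SourceGroup(name=name, mu={"d13C": mu}, omega={"d13C": omega},
                       q={"d13C": q}, n=5)


TDF0 = DiscriminationFactor(lam={"d13C": 5.0, "d15N": 3.0, "d34S": 1.0},
                            tau={"d13C": 0.0, "d15N": 0.0, "d34S": 0.0})


class TestLogPosterior:
    def test_equal_concentrations_reduce_to_plain_model(self):
        """With all q equal the concentration weights cancel (p' = p); the
        log density must match an independently coded plain-mixing density."""
        rng = np.random.default_rng(0)
        x = rng.normal(-20, 1, (8, 2))
        srcs_eq = [
            SourceGroup("a", {"d13C": -28.0, "d15N": 2.0},
                        {"d13C": 0.5, "d15N": 0.5}, {"d13C": 0.4, "d15N": 0.4}),
            SourceGroup("b", {"d13C": -14.0, "d15N": 12.0},
                        {"d13C": 0.5, "d15N": 0.5}, {"d13C": 0.4, "d15N": 0.4}),
        ]
        p = np.array([0.3, 0.7])
        sigma = np.array([0.8, 1.2])
        tdf = DiscriminationFactor(lam={"d13C": 5.0, "d15N": 3.0},
                                   tau={"d13C": 1.5, "d15N": 1.5})
        got = log_posterior(p, sigma, x, srcs_eq, tdf, alpha=1.0, sigma_upper=20.0)
        # independent plain-model computation
        mu = np.array([[-28.0, 2.0], [-14.0, 12.0]])
        lam = np.array([5.0, 3.0])
        om2 = np.full((2, 2), 0.25)
        tau2 = np.full(2, 2.25)
        m = (p[:, None] * (mu + lam)).sum(0)
        v = ((p**2)[:, None] * (om2 + tau2)).sum(0) + sigma**2
        expected = stats.norm.logpdf(x, m, np.sqrt(v)).sum()
        expected += math.lgamma(2.0)  # Dirichlet(1,1) normaliser
        expected += -2 * math.log(20.0)  # sigma prior
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_source_predicts_mu_plus_lambda(self):
        src = [SourceGroup("only", {"d13C": -24.0}, {"d13C": 0.0}, {"d13C": 0.5})]
        x = np.array([[-19.0]])  # exactly mu + lambda
        lp_at_pred = log_posterior(np.array([1.0]), np.array([0.5]), x, src, TDF0)
        x_off = np.array([[-18.0]])
        lp_off = log_posterior(np.array([1.0]), np.array([0.5]), x_off, src, TDF0)
        assert lp_at_pred > lp_off  # density peaks at mu + lambda

    def test_outside_support_is_minus_inf(self):
        src = [one_channel_group("a", -28.0), one_channel_group("b", -14.0)]
        x = np.array([[-20.0]])
        assert log_posterior(np.array([0.5, 0.5]), np.array([-1.0]), x, src, TDF0) == -np.inf
        assert log_posterior(np.array([0.7, 0.7]), np.array([1.0]), x, src, TDF0) == -np.inf

    def test_channel_mismatch_raises_before_arithmetic(self):
        srcs = [
            SourceGroup("a", {"d13C": -28.0}, {"d13C": 0.5}, {"d13C": 0.4}),
            SourceGroup("b", {"d13C": -14.0, "d15N": 10.0},
                        {"d13C": 0.5, "d15N": 0.5}, {"d13C": 0.4, "d15N": 0.4}),
        ]
        with pytest.raises(ValueError):
            MixingProblem(np.array([[-20.0]]), srcs)

    def test_two_source_one_channel_grid_oracle(self):
        """ω=τ=0, σ small: the likelihood in p1 peaks at the algebraic
        concentration-weighted inversion; verified by 10⁴-point grid search."""
        qa, qb = 0.6, 0.3
        mua, mub = -28.0, -14.0
        lam = 5.0
        srcs = [one_channel_group("a", mua, q=qa), one_channel_group("b", mub, q=qb)]
        xbar = -20.0
        x = np.array([[xbar]])
        sigma = np.array([0.05])

        def ll(p1):
            return log_posterior(np.array([p1, 1 - p1]), sigma, x, srcs, TDF0)

        grid = np.linspace(1e-6, 1 - 1e-6, 10_000)
        p_grid = grid[np.argmax([ll(p) for p in grid])]
        # algebraic inversion: mass-balance weight then un-weight by q
        w = (xbar - (mub + lam)) / ((mua + lam) - (mub + lam))
        p_alg = (w / qa) / (w / qa + (1 - w) / qb)
        assert p_grid == pytest.approx(p_alg, abs=2e-4)


class TestSampler:
    def test_recovery_three_sources(self):
        """K=3 well-separated sources, truth p=(0.6,0.3,0.1), n=30 consumers
        generated from the forward model: posterior means within ±0.07 of
        truth, seed-averaged over 5 seeds."""
        srcs = [make_source_group("a", -30.0, 0.0, 2.0, omega=0.4,
                                  q=(0.45, 0.03, 0.002)),
                make_source_group("b", -20.0, 8.0, 10.0, omega=0.4,
                                  q=(0.45, 0.10, 0.006)),
                make_source_group("c", -12.0, 16.0, 18.0, omega=0.4,
                                  q=(0.50, 0.15, 0.010))]
        truth = np.array([0.6, 0.3, 0.1])
        tdf = DiscriminationFactor()
        lam = np.array([5.0, 3.0, 1.0])
        tau2 = np.array([1.5, 1.5, 0.5]) ** 2
        mu = np.array([[g.mu[c] for c in ("d13C", "d15N", "d34S")] for g in srcs])
        q = np.array([[g.q[c] for c in ("d13C", "d15N", "d34S")] for g in srcs])
        om2 = np.full((3, 3), 0.16)
        pq = truth[:, None] * q
        pp = pq / pq.sum(0)
        m = (pp * (mu + lam)).sum(0)
        v = (pp**2 * (om2 + tau2)).sum(0) + 0.2**2
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(m, np.sqrt(v), size=(30, 3))
            cfg = MixingModelConfig(n_iter=30_000, burn_in=6_000, seed=seed)
            res = fit_mixing_model(x, srcs, tdf, cfg)
            means = np.array([res.summaries[g.name]["mean"] for g in srcs])
            errs.append(means - truth)
        avg = np.abs(np.mean(errs, axis=0))
        assert avg.max() <= 0.07

    def test_no_information_limit_recovers_prior(self):
        """Enormous source spread relative to separation: posterior ≈
        Dirichlet(1) prior, mean 1/K per source."""
        srcs = [make_source_group("a", -20.0, 8.0, 10.0, omega=50.0),
                make_source_group("b", -20.5, 8.2, 10.1, omega=50.0),
                make_source_group("c", -21.0, 8.4, 10.2, omega=50.0)]
        x = np.full((5, 3), -16.0)
        cfg = MixingModelConfig(n_iter=30_000, burn_in=6_000, seed=3)
        res = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        for name in res.source_names:
            assert res.summaries[name]["mean"] == pytest.approx(1 / 3, abs=0.05)

    def test_zero_consumers_reproduce_dirichlet_prior(self):
        srcs = [make_source_group("a", -30.0, 0.0, 2.0),
                make_source_group("b", -20.0, 8.0, 10.0),
                make_source_group("c", -12.0, 16.0, 18.0)]
        x = np.empty((0, 3))
        cfg = MixingModelConfig(n_iter=40_000, burn_in=8_000, seed=5)
        res = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        draws = res.p_flat
        # Dirichlet(1,1,1): mean 1/3, var = 2/(9*4) = 1/18
        assert np.allclose(draws.mean(0), 1 / 3, atol=0.03)
        assert np.allclose(draws.var(0), 1 / 18, atol=0.012)

    def test_every_draw_on_simplex(self):
        srcs = [make_source_group("a", -30.0, 0.0, 2.0),
                make_source_group("b", -12.0, 16.0, 18.0)]
        rng = np.random.default_rng(0)
        x = rng.normal(-18, 1, (10, 3))
        cfg = MixingModelConfig(n_iter=5_000, burn_in=1_000, seed=1)
        res = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        assert np.all(res.p_flat >= 0)
        assert np.abs(res.p_flat.sum(axis=1) - 1).max() <= 1e-12

    def test_label_permutation_symmetry(self):
        srcs = [make_source_group("a", -30.0, 0.0, 2.0, q=(0.4, 0.02, 0.002)),
                make_source_group("b", -20.0, 8.0, 10.0, q=(0.45, 0.10, 0.006)),
                make_source_group("c", -12.0, 16.0, 18.0, q=(0.5, 0.15, 0.01))]
        rng = np.random.default_rng(2)
        x = rng.normal([-18.0, 7.0, 9.0], 0.8, (20, 3))
        cfg = MixingModelConfig(n_iter=40_000, burn_in=8_000, seed=7)
        res_fwd = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        res_rev = fit_mixing_model(x, srcs[::-1], DiscriminationFactor(), cfg)
        for name in ("a", "b", "c"):
            assert res_fwd.summaries[name]["mean"] == pytest.approx(
                res_rev.summaries[name]["mean"], abs=0.03)

    def test_deterministic_given_seed(self):
        srcs = [make_source_group("a", -30.0, 0.0, 2.0),
                make_source_group("b", -12.0, 16.0, 18.0)]
        rng = np.random.default_rng(0)
        x = rng.normal(-18, 1, (6, 3))
        cfg = MixingModelConfig(n_iter=4_000, burn_in=1_000, seed=11)
        r1 = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        r2 = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        assert np.array_equal(r1.draws_p, r2.draws_p)

    def test_thinning_caps_stored_draws(self):
        srcs = [make_source_group("a", -30.0, 0.0, 2.0),
                make_source_group("b", -12.0, 16.0, 18.0)]
        x = np.full((4, 3), -20.0)
        cfg = MixingModelConfig(n_iter=60_000, burn_in=10_000, seed=0,
                                max_stored=2_000)
        res = fit_mixing_model(x, srcs, DiscriminationFactor(), cfg)
        assert res.p_flat.shape[0] <= 2_000
        assert res.thin == 50


class TestPosteriorSummaries:
    def test_mode_of_constant_draws(self):
        assert posterior_mode(np.full(2000, 0.5)) == 0.5

    def test_mode_of_beta_draws_matches_closed_form(self):
        rng = np.random.default_rng(0)
        draws = rng.beta(2, 5, 100_000)
        assert posterior_mode(draws) == pytest.approx(0.2, abs=0.02)

    def test_bimodal_mode_picks_taller_peak(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate([rng.normal(0.2, 0.02, 30_000),
                                rng.normal(0.8, 0.02, 60_000)])
        assert posterior_mode(draws) == pytest.approx(0.8, abs=0.03)

    def test_hdr_of_tight_normal(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0.5, 0.01, 100_000)
        (lo, hi), = hdr(draws, 0.95)
        assert lo == pytest.approx(0.5 - 1.96 * 0.01, abs=0.003)
        assert hi == pytest.approx(0.5 + 1.96 * 0.01, abs=0.003)

    def test_hdr_nesting(self):
        rng = np.random.default_rng(3)
        draws = rng.beta(3, 2, 20_000)

        def contains(outer, inner):
            return all(any(ol <= il and ih <= oh for ol, oh in outer)
                       for il, ih in inner)

        h50, h75, h95 = hdr(draws, 0.5), hdr(draws, 0.75), hdr(draws, 0.95)
        assert contains(h75, h50) and contains(h95, h75)

    def test_hdr_of_uniform_draws_near_flat_limit(self):
        """Flat density: HDR(95) length ≈ 0.95; the Gaussian-KDE boundary
        bias trims the edges slightly (measured ≈ 0.93 at n=10⁵)."""
        rng = np.random.default_rng(4)
        draws = rng.random(100_000)
        total = sum(b - a for a, b in hdr(draws, 0.95))
        assert total == pytest.approx(0.95, abs=0.03)

    def test_hdr_multimodal_splits_into_intervals(self):
        rng = np.random.default_rng(5)
        draws = np.concatenate([rng.normal(0.15, 0.02, 50_000),
                                rng.normal(0.85, 0.02, 50_000)])
        assert len(hdr(draws, 0.95)) == 2


class TestOverlapLetters:
    def test_disjoint_get_distinct_letters(self):
        out = hdr_overlap_letters([[(0.1, 0.2)], [(0.5, 0.6)]], ["P1", "P2"])
        assert out == {"P1": "a", "P2": "b"}

    def test_identical_share_a_letter(self):
        out = hdr_overlap_letters([[(0.3, 0.5)], [(0.3, 0.5)]], ["P1", "P2"])
        assert out == {"P1": "a", "P2": "a"}

    def test_path_graph_compact_letter_display(self):
        out = hdr_overlap_letters(
            [[(0.10, 0.30)], [(0.25, 0.55)], [(0.50, 0.80)]], ["P1", "P2", "P3"])
        assert out == {"P1": "a", "P2": "ab", "P3": "b"}

    def test_multi_interval_hdrs_overlap_on_any_piece(self):
        a = [(0.1, 0.2), (0.7, 0.8)]
        b = [(0.75, 0.9)]
        out = hdr_overlap_letters([a, b], ["x", "y"])
        assert out["x"] == out["y"]
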
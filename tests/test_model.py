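"""Likelihood terms, priors, and the augmented Gibbs updates."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import digamma

from voxseg import model as M
from voxseg.model import (
    AugmentedState,
    CountMatrix,
    ModelParams,
    PriorConfig,
    delta_log_likelihood,
    log_likelihood,
    nuclear_log_prior_ratio,
    pg_mean,
    sample_alpha_and_h,
    sample_beta,
    sample_component_assignments,
    sample_crt,
    sample_polya_gamma,
    sample_rates,
    sample_volume_params,
    volume_log_prior,
)


def _params(m, n, k, rng, tau=None):
    p = ModelParams.initial(m, n, PriorConfig(k=k), rng)
    if tau is not None:
        p.tau = tau
    return p


class TestLogLikelihood:
    def test_no_transcripts_closed_form(self, rng):
        m, n = 3, 1
        p = _params(m, n, 1, rng, tau=np.full((m, n), 0.2))
        p.tau_bg = np.full(m, 0.01)
        counts = CountMatrix(np.zeros((m, n), np.int64), np.zeros(m, np.int64))
        nu, vtot = 5.0, 20.0
        got = log_likelihood(np.array([nu]), counts, p, vtot)
        expect = -sum(nu * (0.01 + 0.2) + 0.01 * (vtot - nu) for _ in range(m))
        assert got == pytest.approx(expect)

    def test_one_transcript_adds_point_term(self, rng):
        m, n = 2, 1
        p = _params(m, n, 1, rng, tau=np.full((m, n), 0.2))
        p.tau_bg = np.full(m, 0.01)
        empty = CountMatrix(np.zeros((m, n), np.int64), np.zeros(m, np.int64))
        one = CountMatrix(np.array([[1], [0]], dtype=np.int64), np.zeros(m, np.int64))
        nu = np.array([5.0])
        assert log_likelihood(nu, one, p, 20.0) - log_likelihood(nu, empty, p, 20.0) == (
            pytest.approx(math.log(0.01 + 0.2))
        )

    def test_matches_term_by_term_brute_force(self, rng):
        m, n = 4, 3
        tau = rng.gamma(2.0, 0.1, (m, n))
        p = _params(m, n, 1, rng, tau=tau)
        p.tau_bg = rng.gamma(1.0, 0.02, m)
        X = rng.poisson(2.0, (m, n)).astype(np.int64)
        X_bg = rng.poisson(1.0, m).astype(np.int64)
        nu = rng.uniform(1, 10, n)
        vtot = 100.0
        got = log_likelihood(nu, CountMatrix(X, X_bg), p, vtot)
        brute = 0.0
        for g in range(m):
            for c in range(n):
                brute += -nu[c] * (p.tau_bg[g] + tau[g, c])
                brute += X[g, c] * math.log(p.tau_bg[g] + tau[g, c])
            brute += -p.tau_bg[g] * (vtot - nu.sum())
            brute += X_bg[g] * math.log(p.tau_bg[g])
        assert got == pytest.approx(brute, rel=1e-12)

    def test_delta_antisymmetric(self, rng):
        m, n = 3, 2
        p = _params(m, n, 1, rng, tau=rng.gamma(2, 0.1, (m, n)))
        genes = np.array([0, 2])
        fwd = delta_log_likelihood(genes, 0, 1, 0.5, p)
        rev = delta_log_likelihood(genes, 1, 0, 0.5, p)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestVolumePrior:
    def test_closed_form_at_mean(self):
        mu, prec = math.log(200.0), 2.0
        nu = math.exp(mu)
        expect = -math.log(nu) + 0.5 * math.log(prec / (2 * math.pi))
        assert volume_log_prior(nu, mu, prec) == pytest.approx(expect)
        # matches scipy's lognorm with sd = 1/sqrt(prec)
        sd = 1 / math.sqrt(prec)
        assert volume_log_prior(150.0, mu, prec) == pytest.approx(
            stats.lognorm.logpdf(150.0, s=sd, scale=math.exp(mu))
        )

    def test_integrates_to_one(self):
        mu, prec = math.log(50.0), 1.5
        val, _ = integrate.quad(
            lambda v: math.exp(volume_log_prior(v, mu, prec)), 1e-3, 1e5, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            volume_log_prior(0.0, 1.0, 1.0)


class TestNuclearPrior:
    def test_unlabeled_is_zero(self):
        assert nuclear_log_prior_ratio(0, 1, -1) == 0.0

    def test_moving_off_nuclear_label(self):
        # leaving the nuclear assignment costs log((1-p)/p) with p=0.8
        got = nuclear_log_prior_ratio(old_cell=3, new_cell=5, nuclear_label=3, p_nuc=0.8)
        assert got == pytest.approx(math.log(0.2 / 0.8))

    def test_antisymmetry_and_nonmatching_ratio(self):
        f = nuclear_log_prior_ratio(3, 5, 3)
        r = nuclear_log_prior_ratio(5, 3, 3)
        assert f == pytest.approx(-r)
        assert nuclear_log_prior_ratio(4, 5, 3) == 0.0  # both non-matching


class TestCRT:
    def test_degenerate_cases(self, rng):
        assert sample_crt(0, 2.0, rng) == 0
        assert np.all(sample_crt(np.ones(500, int), 0.7, rng) == 1)
        l = sample_crt(np.full(300, 9), 1.3, rng)
        assert np.all((l >= 1) & (l <= 9))

    @pytest.mark.parametrize("n,r", [(5, 0.5), (17, 2.5), (60, 8.0)])
    def test_mean_matches_digamma_formula(self, n, r, rng):
        draws = sample_crt(np.full(200_000, n), r, rng)
        expect = r * (digamma(r + n) - digamma(r))
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - expect) < 3 * se

    def test_negative_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_crt(-1, 1.0, rng)


class TestPolyaGamma:
    @pytest.mark.parametrize("b,c", [(1.0, 0.0), (2.0, 1.0), (0.5, 3.0), (30.0, 2.0), (80.0, 0.5)])
    def test_mean_matches_closed_form(self, b, c, rng):
        w = sample_polya_gamma(np.full(200_000, b), c, rng)
        assert np.all(w > 0)
        se = w.std() / math.sqrt(len(w))
        assert abs(w.mean() - pg_mean(b, c)) < 3 * se

    def test_mean_decreases_in_c(self):
        grid = np.linspace(0, 6, 25)
        means = pg_mean(2.0, grid)
        assert np.all(np.diff(means) < 0)

    def test_positive_shape_required(self, rng):
        with pytest.raises(ValueError):
            sample_polya_gamma(0.0, 1.0, rng)


class TestComponentAssignments:
    def test_k1_trivial(self, rng):
        counts = CountMatrix(rng.poisson(3, (4, 6)).astype(np.int64), np.zeros(4, np.int64))
        p = _params(4, 6, 1, rng)
        z = sample_component_assignments(counts, np.full(6, 5.0), p, rng)
        assert np.all(z == 0)

    def test_symmetric_components_half_half(self, rng):
        m, n = 3, 400
        p = _params(m, n, 2, rng)
        p.alpha[:] = 2.0
        p.phi[:] = 0.0
        p.pi = np.array([0.5, 0.5])
        counts = CountMatrix(rng.poisson(2, (m, n)).astype(np.int64), np.zeros(m, np.int64))
        z = sample_component_assignments(counts, np.full(n, 3.0), p, rng)
        frac = z.mean()
        assert abs(frac - 0.5) < 3 * 0.5 / math.sqrt(n)

    def test_matches_enumerated_posterior(self, rng):
        """2 genes, 2 components: draw frequencies match the brute-force
        normalized posterior within Monte-Carlo error."""
        m, n, k = 2, 1, 2
        p = _params(m, n, k, rng)
        p.alpha = np.array([[2.0, 0.5], [0.5, 2.0]])
        p.phi = -np.log(np.array([[4.0, 1.0], [1.0, 4.0]]))
        p.pi = np.array([0.3, 0.7])
        X = np.array([[3], [1]], dtype=np.int64)
        counts = CountMatrix(X, np.zeros(m, np.int64))
        nu = np.array([2.0])

        def nb_pmf(x, a, beta):
            pr = nu[0] / (nu[0] + beta)
            return math.exp(
                math.lgamma(x + a) - math.lgamma(a) - math.lgamma(x + 1)
            ) * (1 - pr) ** a * pr**x

        w = np.array(
            [
                p.pi[t] * np.prod([nb_pmf(X[g, 0], p.alpha[g, t], np.exp(-p.phi[g, t])) for g in range(m)])
                for t in range(k)
            ]
        )
        w /= w.sum()
        draws = np.array(
            [sample_component_assignments(counts, nu, p, rng)[0] for _ in range(50_000)]
        )
        frac1 = (draws == 1).mean()
        se = math.sqrt(w[1] * (1 - w[1]) / len(draws))
        assert abs(frac1 - w[1]) < 3 * se


class TestRates:
    def test_posterior_moments(self, rng):
        # 100k iid replicate cells with identical (X, nu): one vectorized draw
        m, n = 1, 100_000
        p = _params(m, n, 1, rng)
        p.alpha[:] = 3.0
        p.phi[:] = -math.log(2.0)  # beta = 2
        p.z = np.zeros(n, dtype=int)
        nu = np.full(n, 4.0)
        X = np.full((m, n), 7, dtype=np.int64)
        sample_rates(CountMatrix(X, np.zeros(1, np.int64)), nu, p, PriorConfig(k=1), 10.0, rng)
        draws = p.tau[0]
        expect = (3.0 + 7) / (2.0 + 4.0)
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - expect) < 3 * se
        assert np.all(draws > 0)

    def test_zero_counts_prior_exposure_draw(self, rng):
        m, n = 2, 3
        p = _params(m, n, 1, rng)
        p.alpha[:] = 5.0
        p.phi[:] = 0.0
        nu = np.full(n, 2.0)
        counts = CountMatrix(np.zeros((m, n), np.int64), np.zeros(m, np.int64))
        means = np.zeros((m, n))
        reps = 4000
        for _ in range(reps):
            sample_rates(counts, nu, p, PriorConfig(k=1), 10.0, rng)
            means += p.tau
        np.testing.assert_allclose(means / reps, 5.0 / 3.0, rtol=0.1)


class TestAlphaBeta:
    def test_empty_component_draws_from_prior(self, rng):
        m, n, k = 2, 4, 2
        prior = PriorConfig(k=k)
        p = _params(m, n, k, rng)
        p.z = np.zeros(n, dtype=int)  # component 1 empty
        counts = CountMatrix(rng.poisson(2, (m, n)).astype(np.int64), np.zeros(m, np.int64))
        alphas, phis = [], []
        for _ in range(3000):
            p.h = 1.0
            sample_alpha_and_h(counts, np.full(n, 2.0), p, prior, rng)
            alphas.append(p.alpha[0, 1])
            p.phi[:] = 0.0
            sample_beta(counts, np.full(n, 2.0), p, prior, rng)
            phis.append(p.phi[0, 1])
        # alpha ~ Gamma(e0, h) with e0 = h = 1 -> mean 1; phi ~ N(0, 1/gamma)
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.1)
        assert np.mean(phis) == pytest.approx(0.0, abs=0.1)
        assert np.std(phis) == pytest.approx(1.0, abs=0.1)

    def test_crt_rate_positive(self, rng):
        """With one cell and X=0 the alpha rate is h + log((nu+beta)/beta)."""
        m, n, k = 1, 1, 1
        prior = PriorConfig(k=k)
        p = _params(m, n, k, rng)
        p.phi[:] = 0.0  # beta = 1
        counts = CountMatrix(np.zeros((m, n), np.int64), np.zeros(m, np.int64))
        nu = np.array([3.0])
        # rate = h + log(4) -> E[alpha] = e0 / (h + log 4)
        draws = []
        for _ in range(20000):
            p.h = 1.0
            sample_alpha_and_h(counts, nu, p, prior, rng)
            draws.append(p.alpha[0, 0])
            p.alpha[:] = 1.0
        assert np.mean(draws) == pytest.approx(1.0 / (1.0 + math.log(4.0)), rel=0.05)


class TestVolumeParams:
    def test_identical_volumes_concentrate_mu(self, rng):
        n, k = 200, 1
        prior = PriorConfig(k=k)
        p = _params(2, n, k, rng)
        v = 150.0
        mus = []
        for _ in range(500):
            sample_volume_params(np.full(n, v), p, prior, rng)
            mus.append(p.mu_vol[0])
        assert np.mean(mus) == pytest.approx(math.log(v), abs=0.05)

    def test_pi_dirichlet_moment(self, rng):
        n, k = 30, 3
        prior = PriorConfig(k=k)
        p = _params(2, n, k, rng)
        p.z = np.repeat([0, 1, 2], 10)
        pis = np.zeros(k)
        reps = 5000
        for _ in range(reps):
            sample_volume_params(np.full(n, 100.0), p, prior, rng)
            pis += p.pi
        np.testing.assert_allclose(pis / reps, (1.0 + 10) / (k + n), rtol=0.05)

    def test_empty_component_prior_draw(self, rng):
        prior = PriorConfig(k=2, mu0=math.log(100.0), sigma0=4.0)
        p = _params(2, 5, 2, rng)
        p.z = np.zeros(5, dtype=int)
        mus = []
        for _ in range(4000):
            p.prec_vol[:] = 1.0
            sample_volume_params(np.full(5, 80.0), p, prior, rng)
            mus.append(p.mu_vol[1])
        assert np.mean(mus) == pytest.approx(math.log(100.0), abs=0.05)


class TestNBMarginal:
    def test_tau_poisson_matches_negative_binomial(self, rng):
        """Counts drawn tau -> Poisson match NB(alpha, nu/(nu+beta)):
        chi-square goodness of fit not rejected at 0.01."""
        alpha, beta, nu = 2.0, 1.5, 2.0
        N = 100_000
        tau = rng.gamma(alpha, 1 / beta, N)
        X = rng.poisson(nu * tau)
        pr = nu / (nu + beta)
        kmax = 15
        obs = np.bincount(np.minimum(X, kmax), minlength=kmax + 1)
        ks = np.arange(kmax)
        pmf = stats.nbinom.pmf(ks, alpha, 1 - pr)
        probs = np.append(pmf, 1 - pmf.sum())
        _, pval = stats.chisquare(obs, probs * N)
        assert pval > 0.01


class TestCountConservation:
    def test_from_assignments_conserves_total(self, rng):
        m, n, M = 5, 4, 1000
        gene = rng.integers(0, m, M)
        cell = rng.integers(-1, n, M)
        cm = CountMatrix.from_assignments(gene, cell, m, n)
        assert cm.M == M
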
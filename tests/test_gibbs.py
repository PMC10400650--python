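import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats
from scipy.stats import norm

from bayeslod.gibbs import (PriorSpec, conjugate_posterior_moments,
                            draw_latent_censored, ess, gibbs_fit,
                            partition_conditional, record_log_likelihood,
                            rhat, sample_truncnorm)
from bayeslod.panel import CellObservation, CellStatus
from bayeslod.simulate import GroupScenario, generate_panel

O, B, I = CellStatus.OBSERVED, CellStatus.BELOW_LIMIT, CellStatus.INTERVAL


def obs(v):
    return CellObservation(O, value=v)


def bl(c):
    return CellObservation(B, limit=c)


def iv(lo, hi):
    return CellObservation(I, lower=lo, upper=hi)


# ----------------------------------------------------------------------
# conditional partition
# ----------------------------------------------------------------------

class TestPartitionConditional:
    def test_identity_covariance_ignores_observed(self):
        mu = np.array([1.0, -2.0, 0.5])
        m, c = partition_conditional(mu, np.eye(3), [0], [1, 2], [5.0])
        np.testing.assert_allclose(m, mu[[1, 2]])
        np.testing.assert_allclose(c, np.eye(2))

    def test_empty_observed_returns_marginal(self):
        mu = np.array([1.0, 2.0])
        sig = np.array([[2.0, 0.5], [0.5, 1.0]])
        m, c = partition_conditional(mu, sig, [], [0, 1], [])
        np.testing.assert_allclose(m, mu)
        np.testing.assert_allclose(c, sig)

    def test_against_grid_conditioning_oracle(self):
        # discretize the bivariate normal, condition numerically on y1=1
        sig = np.array([[1.0, 0.5], [0.5, 1.0]])
        m, c = partition_conditional(np.zeros(2), sig, [0], [1], [1.0])
        y2 = np.linspace(-8, 8, 4001)
        dens = stats.multivariate_normal(np.zeros(2), sig).pdf(
            np.column_stack([np.full_like(y2, 1.0), y2]))
        w = dens / dens.sum()
        grid_mean = np.sum(w * y2)
        grid_var = np.sum(w * (y2 - grid_mean) ** 2)
        assert abs(m[0] - grid_mean) < 1e-6
        assert abs(c[0, 0] - grid_var) < 1e-6

    def test_singular_block_reports_condition(self):
        sig = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            partition_conditional(np.zeros(3), sig, [0, 1], [2], [0.0, 0.0])

    def test_conditional_cov_symmetric_psd(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        sig = A @ A.T + 0.5 * np.eye(4)
        _, c = partition_conditional(np.zeros(4), sig, [0, 2], [1, 3], [0.3, -0.2])
        np.testing.assert_allclose(c, c.T)
        assert np.all(np.linalg.eigvalsh(c) > -1e-10)


# ----------------------------------------------------------------------
# censored likelihood
# ----------------------------------------------------------------------

class TestRecordLogLikelihood:
    def test_fully_observed_equals_mvn_logpdf(self):
        mu = np.array([0.5, -1.0])
        sig = np.array([[1.0, 0.4], [0.4, 2.0]])
        cells = [obs(2.0), obs(0.3)]
        y = np.log([2.0, 0.3])
        expected = stats.multivariate_normal.logpdf(y, mu, sig)
        assert record_log_likelihood(mu, sig, cells) == pytest.approx(expected, rel=1e-12)

    def test_univariate_censored_is_log_cdf(self):
        # single below-limit cell at c with mu=0, var=1 -> log Phi(log c)
        for c in (0.5, 1.0, 3.0):
            got = record_log_likelihood(np.zeros(1), np.eye(1), [bl(c)])
            assert got == pytest.approx(norm.logcdf(np.log(c)), rel=1e-12)

    @pytest.mark.parametrize("rho,c2", [(0.7, 1.0), (0.7, 0.3), (-0.5, 2.0)])
    def test_mixed_case_matches_quadrature(self, rho, c2):
        # one observed, one censored: integrate the bivariate normal density
        # over the censored region with adaptive quadrature
        mu = np.array([0.2, -0.1])
        sig = np.array([[1.0, rho], [rho, 1.0]])
        x1 = 1.7
        cells = [obs(x1), bl(c2)]
        mvn = stats.multivariate_normal(mu, sig)
        val, err = integrate.quad(
            lambda y2: mvn.pdf([np.log(x1), y2]), -30, np.log(c2), epsabs=1e-12)
        got = record_log_likelihood(mu, sig, cells)
        assert got == pytest.approx(np.log(val), abs=1e-6)

    def test_interval_cell_matches_quadrature(self):
        mu = np.array([0.0, 0.0])
        sig = np.array([[1.0, 0.6], [0.6, 1.0]])
        cells = [obs(1.5), iv(0.5, 2.5)]
        mvn = stats.multivariate_normal(mu, sig)
        val, _ = integrate.quad(lambda y2: mvn.pdf([np.log(1.5), y2]),
                                np.log(0.5), np.log(2.5), epsabs=1e-12)
        assert record_log_likelihood(mu, sig, cells) == pytest.approx(np.log(val), abs=1e-6)

    def test_two_censored_cells_match_double_quadrature(self):
        sig = np.array([[1.0, 0.5], [0.5, 1.0]])
        cells = [bl(1.2), bl(0.7)]
        mvn = stats.multivariate_normal(np.zeros(2), sig)
        val, _ = integrate.dblquad(lambda y2, y1: mvn.pdf([y1, y2]),
                                   -30, np.log(1.2), -30, np.log(0.7), epsabs=1e-11)
        assert record_log_likelihood(np.zeros(2), sig, cells) == pytest.approx(
            np.log(val), abs=1e-5)

    @given(st.floats(0.1, 5.0), st.floats(0.05, 0.9))
    def test_monotone_in_detection_limit(self, c, bump):
        # CDF monotonicity: raising a below-limit cell's limit cannot
        # decrease the likelihood
        mu = np.array([0.0, 0.3])
        sig = np.array([[1.0, 0.4], [0.4, 0.8]])
        lo = record_log_likelihood(mu, sig, [obs(1.0), bl(c)])
        hi = record_log_likelihood(mu, sig, [obs(1.0), bl(c + bump)])
        assert hi >= lo - 1e-9


# ----------------------------------------------------------------------
# truncated-normal sampling / latent updates
# ----------------------------------------------------------------------

class TestTruncatedNormal:
    @given(st.floats(-30, 30), st.floats(0.2, 4), st.floats(-40, 40), st.floats(0.1, 20))
    def test_draws_respect_bounds(self, mean, sd, lo, width):
        rng = np.random.default_rng(1234)
        x = sample_truncnorm(rng, np.full(50, lo), np.full(50, lo + width), mean, sd)
        assert np.all(x >= lo) and np.all(x <= lo + width)

    def test_far_tail_draws_finite(self):
        rng = np.random.default_rng(0)
        x = sample_truncnorm(rng, np.full(100, -np.inf), np.full(100, -15.0))
        assert np.all(np.isfinite(x)) and np.all(x <= -15.0)
        x = sample_truncnorm(rng, np.full(100, 15.0), np.full(100, np.inf))
        assert np.all(np.isfinite(x)) and np.all(x >= 15.0)

    def test_halfnormal_mean_closed_form(self):
        # truncation at 0 from above: E[Z | Z<0] = -phi(0)/Phi(0) = -0.7979
        rng = np.random.default_rng(7)
        x = sample_truncnorm(rng, np.full(50_000, -np.inf), np.zeros(50_000))
        expected = -norm.pdf(0) / norm.cdf(0)
        assert abs(x.mean() - expected) < 4 * x.std() / np.sqrt(x.size)

    def test_untruncated_matches_normal(self):
        rng = np.random.default_rng(7)
        x = sample_truncnorm(rng, np.full(50_000, -np.inf), np.full(50_000, np.inf), 2.0, 3.0)
        assert abs(x.mean() - 2.0) < 4 * 3.0 / np.sqrt(x.size)


class TestDrawLatentCensored:
    def test_bounds_respected_and_observed_pinned(self):
        rng = np.random.default_rng(0)
        mu = np.zeros(3)
        sig = np.eye(3) + 0.4 - 0.4 * np.eye(3)
        cells = [obs(2.0), bl(0.8), iv(0.5, 1.5)]
        cur = np.log([2.0, 0.5, 1.0])
        for _ in range(200):
            cur = draw_latent_censored(mu, sig, cells, cur, rng)
            assert cur[0] == pytest.approx(np.log(2.0))
            assert cur[1] <= np.log(0.8)
            assert np.log(0.5) <= cur[2] <= np.log(1.5)

    def test_no_truncation_recovers_conditional_mean(self):
        # interval so wide it never binds: draws average to the
        # conditional normal mean given the observed coordinate
        rng = np.random.default_rng(1)
        mu = np.zeros(2)
        sig = np.array([[1.0, 0.6], [0.6, 1.0]])
        cells = [obs(np.exp(1.0)), iv(1e-8, 1e8)]
        cur = np.log([np.exp(1.0), 1.0])
        draws = np.array([draw_latent_censored(mu, sig, cells, cur, rng)[1]
                          for _ in range(50_000)])
        cond_mean, cond_var = 0.6 * 1.0, 1 - 0.36
        assert abs(draws.mean() - cond_mean) < 4 * np.sqrt(cond_var / draws.size)


# ----------------------------------------------------------------------
# the Gibbs fit
# ----------------------------------------------------------------------

def _uncensored_panel(J, n, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((J, J))
    sig = A @ A.T / J + 0.3 * np.eye(J)
    mu = rng.standard_normal(J)
    scn = GroupScenario(mu=mu, sigma=sig, n=n)
    return generate_panel(scn, GroupScenario(mu=mu, sigma=sig, n=2), "cord",
                          seed=seed).subset(group="ASD")


class TestGibbsFit:
    def test_conjugate_oracle_fully_observed(self):
        panel = _uncensored_panel(J=2, n=80, seed=4)
        prior = PriorSpec.from_panel(panel)
        draws, rep = gibbs_fit(panel, prior=prior, n_chains=2, n_iter=3500,
                               n_burnin=1000, seed=0)
        Y = np.log(panel.value)
        m_exact, S_exact = conjugate_posterior_moments(prior, Y)
        se = draws.mu.std(0) / np.sqrt(len(draws))  # draws iid when uncensored
        assert np.all(np.abs(draws.mu.mean(0) - m_exact) < 3 * se)
        se_S = draws.sigma.std(0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.sigma.mean(0) - S_exact) < 3.5 * se_S)
        assert rep.passed

    def test_uncensored_limit_matches_conjugate_sampling(self):
        # kolmogorov distance between gibbs mu draws and direct draws from
        # the closed-form conjugate posterior
        panel = _uncensored_panel(J=2, n=80, seed=8)
        prior = PriorSpec.from_panel(panel)
        draws, _ = gibbs_fit(panel, prior=prior, n_chains=2, n_iter=6000,
                             n_burnin=1000, seed=1)
        from bayeslod.gibbs import _niw_posterior
        mn, kn, nun, Sn = _niw_posterior(prior, np.log(panel.value))
        rng = np.random.default_rng(5)
        sig = stats.invwishart.rvs(df=nun, scale=Sn, size=10_000, random_state=rng)
        mu0 = mn[0] + np.sqrt(sig[:, 0, 0] / kn) * rng.standard_normal(10_000)
        ks = stats.ks_2samp(draws.mu[:, 0], mu0).statistic
        assert ks < 0.05

    def test_seed_determinism(self):
        panel = _uncensored_panel(J=2, n=20, seed=3)
        a, _ = gibbs_fit(panel, n_chains=2, n_iter=200, n_burnin=100, seed=9)
        b, _ = gibbs_fit(panel, n_chains=2, n_iter=200, n_burnin=100, seed=9)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_censored_fit_recovers_truth(self):
        mu = np.array([0.0, 0.7])
        sig = np.array([[0.6, 0.2], [0.2, 0.5]])
        scn = GroupScenario(mu=mu, sigma=sig, n=150,
                            detection_limits=np.exp(mu - 0.2))
        panel = generate_panel(scn, GroupScenario(mu=mu, sigma=sig, n=2),
                               "cord", seed=10).subset(group="ASD")
        draws, rep = gibbs_fit(panel, n_chains=2, n_iter=2500, n_burnin=1000, seed=2)
        assert rep.passed
        lo, hi = np.quantile(draws.mu, [0.005, 0.995], axis=0)
        assert np.all(lo < mu) and np.all(mu < hi)

    def test_metal_order_equivariance(self):
        mu = np.array([0.0, 0.9])
        sig = np.array([[0.5, 0.25], [0.25, 0.7]])
        scn = GroupScenario(mu=mu, sigma=sig, n=120,
                            detection_limits=np.exp(mu), metals=["A", "B"])
        panel = generate_panel(scn, GroupScenario(mu=mu, sigma=sig, n=2, metals=["A", "B"]),
                               "cord", seed=6).subset(group="ASD")
        perm = panel.subset()
        order = [1, 0]
        perm.metals = [panel.metals[j] for j in order]
        for fld in ("status", "value", "limit", "lower", "upper"):
            setattr(perm, fld, getattr(panel, fld)[:, order])
        d1, _ = gibbs_fit(panel, n_chains=2, n_iter=2500, n_burnin=1000, seed=3)
        d2, _ = gibbs_fit(perm, n_chains=2, n_iter=2500, n_burnin=1000, seed=4)
        # same posterior up to relabeling (Monte-Carlo tolerance)
        se = d1.mu.std(0) / 25  # generous: draws autocorrelated
        np.testing.assert_allclose(d1.mu.mean(0), d2.mu.mean(0)[order], atol=6 * max(se))

    def test_degenerate_inputs_rejected(self):
        from conftest import make_panel
        single = make_panel([[CellStatus.OBSERVED]], value=[[1.0]], groups=["ASD"])
        with pytest.raises(ValueError, match="at least 2"):
            gibbs_fit(single, n_iter=10, n_burnin=5, seed=0)
        panel = _uncensored_panel(J=2, n=10, seed=3)
        with pytest.raises(ValueError, match="n_burnin"):
            gibbs_fit(panel, n_iter=10, n_burnin=20, seed=0)


class TestDiagnostics:
    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 5000))
        assert 1.0 <= rhat(chains) < 1.01

    def test_iid_chains_ess_near_total(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 2500))
        assert abs(ess(chains) - 10_000) < 2000

    def test_shifted_chain_flags_nonconvergence(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(1000)
        chains = np.stack([base, base + 10.0])
        assert rhat(chains) > 1.1

    def test_constant_chains_rhat_nan(self):
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            r = rhat(np.ones((2, 100)))
        assert np.isnan(r)


class TestPriorSpec:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive definite"):
            PriorSpec(m0=np.zeros(2), kappa0=0.01, nu0=4,
                      S0=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="nu0"):
            PriorSpec(m0=np.zeros(3), kappa0=0.01, nu0=1.5, S0=np.eye(3))
        with pytest.raises(ValueError, match="kappa0"):
            PriorSpec(m0=np.zeros(2), kappa0=0.0, nu0=4, S0=np.eye(2))

    def test_from_panel_uses_log_midranges(self, toy_panel):
        prior = PriorSpec.from_panel(toy_panel)
        # Al: observed 5, 2, 3 and interval (0, 50] -> midpoint of log values
        vals = [np.log(5), np.log(2), np.log(3), np.log(50) - 1.0]
        assert prior.m0[0] == pytest.approx((min(vals) + max(vals)) / 2)
        assert prior.nu0 == toy_panel.J + 2
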
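"""Zero-adjusted Poisson machinery and the environmental null model."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from phenostate.generator import GeneratorParams, generate_abundance_table, \
    generate_environment
from phenostate.nullmodel import (fit_zap, null_relev_ensemble, sample_zap,
                                  spearman_coupling_test,
                                  truncated_poisson_mean_root, zap_pmf)


class TestZapPmf:
    def test_degenerate_zero_mass(self):
        assert zap_pmf(1.0, 5.0, 0) == 1.0
        assert zap_pmf(1.0, 5.0, 3) == 0.0

    def test_normalization(self):
        total = sum(zap_pmf(0.3, 4.0, k) for k in range(201))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value(self):
        expect = 0.8 * np.exp(-1) / (1 - np.exp(-1))   # ~0.46553
        assert zap_pmf(0.2, 1.0, 1) == pytest.approx(expect, abs=1e-12)

    def test_large_mu_stable(self):
        p = zap_pmf(0.1, 600.0, 600)
        assert np.isfinite(p) and p > 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            zap_pmf(0.2, 0.0, 1)
        with pytest.raises(ValueError):
            zap_pmf(1.2, 1.0, 1)
        with pytest.raises(ValueError):
            zap_pmf(0.2, 1.0, -1)


class TestSampleZap:
    def test_all_zero_when_pi0_is_one(self):
        rng = np.random.default_rng(0)
        assert not sample_zap(np.ones(100), np.full(100, 4.0), rng).any()

    def test_matches_pmf_by_chi_square(self):
        rng = np.random.default_rng(1)
        draws = sample_zap(np.full(100_000, 0.3), np.full(100_000, 4.0), rng)
        kmax = 14
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        exp = np.array([zap_pmf(0.3, 4.0, k) for k in range(kmax)])
        exp = np.append(exp, 1 - exp.sum()) * draws.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, kmax) > 0.01

    def test_seeded_stream_reproducible(self):
        a = sample_zap(np.full(50, 0.4), np.full(50, 3.0), np.random.default_rng(7))
        b = sample_zap(np.full(50, 0.4), np.full(50, 3.0), np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestFitZap:
    def test_intercept_only_zero_part_is_empirical_fraction(self):
        rng = np.random.default_rng(2)
        pos = rng.poisson(4.0, 300)
        y = np.concatenate([np.zeros(40), pos[pos > 0][:60]])
        m = fit_zap(y)
        assert m.pi0_intercept == np.mean(y == 0)
        assert expit(m.zero_coef[0]) == pytest.approx(np.mean(y == 0), abs=1e-12)

    def test_intercept_only_positive_part_matches_root_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.poisson(5.0, 400)
        y = np.concatenate([np.zeros(70), pos[pos > 0][:200]])
        m = fit_zap(y)
        mu_oracle = truncated_poisson_mean_root(float(y[y > 0].mean()))
        assert np.exp(m.pos_coef[0]) == pytest.approx(mu_oracle, abs=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="positive part"):
            fit_zap(np.zeros(50))

    def test_hurdle_loglik_separates(self):
        p = GeneratorParams(n_plots=800, seed=30)
        env = generate_environment(p)
        tab = generate_abundance_table(env, p)
        pcs = np.array([e.env_pcs for e in env])
        m = fit_zap(tab.ev_count.to_numpy(), pcs)
        assert m.llf == pytest.approx(m.llf_zero + m.llf_pos)
        assert m.converged

    def test_parameter_recovery_on_generator_output(self):
        p = GeneratorParams(n_plots=2000, seed=21)
        env = generate_environment(p)
        tab = generate_abundance_table(env, p)
        pcs = np.array([e.env_pcs for e in env])
        m = fit_zap(tab.ev_count.to_numpy(), pcs)
        from phenostate.generator import abundance_zap_params
        pi0_true, _, log_mu_true, _ = abundance_zap_params(p, pcs)
        pi0_hat, mu_hat = m.predict(pcs)
        assert np.abs(pi0_hat - pi0_true).mean() < 0.05
        rel = np.abs(mu_hat - np.exp(log_mu_true)).mean() / np.exp(log_mu_true).mean()
        assert rel < 0.10


@pytest.fixture(scope="module")
def fitted_uncoupled():
    p = GeneratorParams(n_plots=1500, seed=55)
    env = generate_environment(p)
    tab = generate_abundance_table(env, p)
    pcs = np.array([e.env_pcs for e in env])
    m_ev = fit_zap(tab.ev_count.to_numpy(), pcs)
    m_de = fit_zap(tab.de_count.to_numpy(), pcs)
    return p, tab, pcs, m_ev, m_de


@pytest.fixture(scope="module")
def fitted_coupled():
    # environment removed from the abundance means: the coupling signal is
    # then pure extra-environmental dependence, which is what the test
    # isolates (with env effects present, the latent-factor overdispersion
    # also dilutes the observed rank correlation, confounding the check)
    p = GeneratorParams(n_plots=1500, seed=56, abundance_coupling=-0.9,
                        abundance_zero_env=0.0, abundance_env=0.0)
    env = generate_environment(p)
    tab = generate_abundance_table(env, p)
    pcs = np.array([e.env_pcs for e in env])
    m_ev = fit_zap(tab.ev_count.to_numpy(), pcs)
    m_de = fit_zap(tab.de_count.to_numpy(), pcs)
    return p, tab, pcs, m_ev, m_de


class TestNullEnsemble:
    def test_histograms_normalized_and_envelope_ordered(self, fitted_uncoupled):
        _, tab, pcs, m_ev, m_de = fitted_uncoupled
        res = null_relev_ensemble(m_ev, m_de, pcs, tab.ev_count.to_numpy(),
                                  tab.de_count.to_numpy(), n_rep=100,
                                  rng=np.random.default_rng(0), dip_n_null=100)
        assert res.observed_freq.sum() == pytest.approx(1.0)
        assert np.all(res.null_q025 <= res.null_q975 + 1e-12)
        assert res.n_replicates == 100

    def test_environment_only_data_stays_inside_envelope(self, fitted_uncoupled):
        _, tab, pcs, m_ev, m_de = fitted_uncoupled
        res = null_relev_ensemble(m_ev, m_de, pcs, tab.ev_count.to_numpy(),
                                  tab.de_count.to_numpy(), n_rep=200,
                                  rng=np.random.default_rng(1), dip_n_null=100)
        assert res.outer_bin_exceeds == (False, False)

    def test_coupled_data_exceeds_outer_envelope(self, fitted_coupled):
        _, tab, pcs, m_ev, m_de = fitted_coupled
        res = null_relev_ensemble(m_ev, m_de, pcs, tab.ev_count.to_numpy(),
                                  tab.de_count.to_numpy(), n_rep=200,
                                  rng=np.random.default_rng(2), dip_n_null=100)
        assert res.outer_bin_exceeds == (True, True)

    def test_widening_the_band_never_creates_an_exceedance(self, fitted_coupled):
        """Envelope monotonicity: a stricter (wider) null band can only
        remove outer-bin exceedances, never add them."""
        _, tab, pcs, m_ev, m_de = fitted_coupled
        rng = np.random.default_rng(3)
        pi_ev, mu_ev = m_ev.predict(pcs)
        pi_de, mu_de = m_de.predict(pcs)
        hists = []
        for _ in range(200):
            ev = sample_zap(pi_ev, mu_ev, rng)
            de = sample_zap(pi_de, mu_de, rng)
            tot = ev + de
            keep = tot >= 10
            h, _ = np.histogram(ev[keep] / tot[keep], bins=np.linspace(0, 1, 21))
            hists.append(h / h.sum())
        H = np.array(hists)
        tot = tab.ev_count + tab.de_count
        keep = tot >= 10
        obs, _ = np.histogram(tab.ev_count[keep] / tot[keep],
                              bins=np.linspace(0, 1, 21))
        obs = obs / obs.sum()
        for b in (0, 19):
            narrow = obs[b] > np.quantile(H[:, b], 0.975)
            wide = obs[b] > np.quantile(H[:, b], 0.995)
            assert narrow or not wide


class TestSpearmanCoupling:
    def test_perfect_reversal_gives_minus_one(self, fitted_uncoupled):
        _, _, pcs, m_ev, m_de = fitted_uncoupled
        ev = np.arange(1.0, 10.0)
        de = ev[::-1]
        rho, _, _ = spearman_coupling_test(ev, de, m_ev, m_de, pcs[:9], n_rep=20,
                                           rng=np.random.default_rng(0))
        assert rho == pytest.approx(-1.0)

    def test_uncoupled_data_not_significant(self, fitted_uncoupled):
        _, tab, pcs, m_ev, m_de = fitted_uncoupled
        _, _, p = spearman_coupling_test(tab.ev_count.to_numpy(),
                                         tab.de_count.to_numpy(),
                                         m_ev, m_de, pcs, n_rep=200,
                                         rng=np.random.default_rng(4))
        assert p > 0.01

    def test_coupled_data_below_every_null_draw(self, fitted_coupled):
        _, tab, pcs, m_ev, m_de = fitted_coupled
        rho, null, p = spearman_coupling_test(tab.ev_count.to_numpy(),
                                              tab.de_count.to_numpy(),
                                              m_ev, m_de, pcs, n_rep=300,
                                              rng=np.random.default_rng(5))
        assert p == 0.0
        assert rho < null.min()

    def test_constant_vector_rejected(self, fitted_uncoupled):
        _, _, pcs, m_ev, m_de = fitted_uncoupled
        with pytest.raises(ValueError, match="constant"):
            spearman_coupling_test(np.ones(20), np.arange(20.0), m_ev, m_de,
                                   pcs[:20], n_rep=10)


def test_refit_on_simulated_replicate_recovers_parameters(fitted_uncoupled):
    """The ensemble reproduces itself: refitting on one simulated replicate
    lands near the generating model."""
    _, _, pcs, m_ev, _ = fitted_uncoupled
    rng = np.random.default_rng(6)
    pi0, mu = m_ev.predict(pcs)
    sim = sample_zap(pi0, mu, rng)
    m2 = fit_zap(sim, pcs)
    pi0_2, mu_2 = m2.predict(pcs)
    assert np.abs(pi0_2 - pi0).mean() < 0.05
    assert np.abs(mu_2 - mu).mean() / mu.mean() < 0.10
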
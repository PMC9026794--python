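import math

import numpy as np
import pytest
from scipy import stats

from tsdnorm.ml_fitting import BinomialDataset, fit_mle
from tsdnorm.posterior_mcmc import (
    McmcConfig,
    ParameterChain,
    PriorSpec,
    default_prior,
    effective_diagnostics,
    run_mcmc,
    summarize_posterior,
    write_chain,
)
from tsdnorm.reaction_norms import LogisticNorm, logistic_sr

TRT_FACTOR = 2 * math.log(19)


def make_data(temps, males, totals):
    return BinomialDataset(np.asarray(temps, float), np.asarray(males, float),
                           np.asarray(totals, float))


def simulate_limb(norm, temps, n_per_temp, seed):
    rng = np.random.default_rng(seed)
    males = rng.binomial(n_per_temp, logistic_sr(norm, np.asarray(temps, float)))
    return make_data(temps, males, [n_per_temp] * len(temps))


class TestSampler:
    def test_same_seed_gives_identical_chains(self, light_config):
        data = simulate_limb(LogisticNorm(27, 1.2), [24, 26, 28, 30], 50, 3)
        prior = default_prior("FM")
        a = run_mcmc(data, "logistic", prior, light_config)
        b = run_mcmc(data, "logistic", prior, light_config)
        assert np.array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate
        s1 = summarize_posterior(a)
        s2 = summarize_posterior(b)
        assert s1 == s2

    def test_draws_respect_prior_bounds(self, light_config):
        data = simulate_limb(LogisticNorm(27, 1.2), [24, 26, 28, 30], 30, 5)
        prior = PriorSpec(P_bounds=(25.0, 29.0), S_bounds=(0.0, 2.0))
        chain = run_mcmc(data, "logistic", prior, light_config)
        assert chain.draws[:, 0].min() > 25.0 and chain.draws[:, 0].max() < 29.0
        assert chain.draws[:, 1].min() > 0.0 and chain.draws[:, 1].max() < 2.0
        assert 0.0 < chain.acceptance_rate < 1.0

    def test_prior_only_recovers_analytic_quantiles(self):
        """With no data the chain must reproduce the prior itself."""
        prior = default_prior("FM")  # P ~ U(20, 35); |S| half-normal(1) on (0, 5)
        config = McmcConfig(seed=9, n_iterations=120_000, burn_in=10_000, thin=10,
                            proposal_sd=(4.0, 0.8))
        chain = run_mcmc(None, "logistic", prior, config)
        n_eff = len(chain) / 8  # generous allowance for autocorrelation
        for q in (0.25, 0.5, 0.75):
            # uniform P quantiles
            expected_p = 20 + 15 * q
            se = 15 * math.sqrt(q * (1 - q) / n_eff)
            assert abs(np.quantile(chain.column("P"), q) - expected_p) < 3 * se
            # half-normal S quantiles (truncation at 5 is negligible)
            expected_s = stats.halfnorm.ppf(q)
            dens = stats.halfnorm.pdf(expected_s)
            se_s = math.sqrt(q * (1 - q) / n_eff) / dens
            assert abs(np.quantile(chain.column("S"), q) - expected_s) < 3 * se_s

    def test_large_data_concentrates_on_mle(self):
        data = simulate_limb(LogisticNorm(27.3, 1.1), [24, 26, 28, 30, 32], 5000, 21)
        mle = fit_mle(data, "logistic", "FM").params.P
        config = McmcConfig(seed=4, n_iterations=20_000, burn_in=4_000,
                            proposal_sd=(0.05, 0.05))
        chain = run_mcmc(data, "logistic", default_prior("FM"), config)
        assert abs(np.median(chain.column("P")) - mle) < 0.05

    def test_posterior_width_shrinks_with_sample_size(self, light_config):
        widths = []
        for n in (20, 200, 2000):
            data = simulate_limb(LogisticNorm(27, 1.2), [24, 26, 28, 30], n, 17)
            chain = run_mcmc(data, "logistic", default_prior("FM"), light_config)
            lo, hi = np.quantile(chain.column("P"), [0.025, 0.975])
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_out_of_bounds_init_rejected(self, light_config):
        with pytest.raises(ValueError):
            run_mcmc(None, "logistic", default_prior("FM"), light_config,
                     init=np.array([50.0, 1.0]))


class TestSummaries:
    def test_constant_chain_collapses(self):
        draws = np.tile([28.0, -1.5], (500, 1))
        chain = ParameterChain(draws, 0.5, ("P", "S"))
        summary = summarize_posterior(chain)
        assert summary.P == (28.0, 28.0, 28.0)
        assert summary.TRT[0] == summary.TRT[2] == pytest.approx(1.5 * TRT_FACTOR)

    def test_trt_is_per_draw_transform_of_scale(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack([rng.normal(30, 1, 4000), -rng.uniform(0.2, 3, 4000)])
        chain = ParameterChain(draws, 0.4, ("P", "S"))
        summary = summarize_posterior(chain)
        expected = TRT_FACTOR * np.quantile(np.abs(draws[:, 1]), [0.025, 0.5, 0.975])
        assert summary.TRT == pytest.approx(tuple(expected))
        assert summary.P[0] <= summary.P[1] <= summary.P[2]
        assert summary.TRT[0] >= 0

    def test_chain_export_round_trips(self, tmp_path):
        draws = np.array([[28.0, 1.0], [28.5, 1.2]])
        chain = ParameterChain(draws, 0.3, ("P", "S"))
        path = tmp_path / "chain.tsv"
        write_chain(chain, path)
        back = np.loadtxt(path, skiprows=1)
        assert np.allclose(back, draws)


class TestDiagnostics:
    def test_white_noise_chain_passes(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(size=(5000, 2))
        report = effective_diagnostics(ParameterChain(draws, 0.5, ("P", "S")))
        assert not report.flagged
        assert all(r < 1.01 for r in report.split_rhat)
        assert all(abs(a) < 0.05 for a in report.lag1_autocorr)

    def test_sticky_chain_flagged(self):
        draws = np.tile([28.0, 1.0], (500, 1))
        report = effective_diagnostics(ParameterChain(draws, 0.001, ("P", "S")))
        assert report.flagged

    def test_drifting_chain_flagged(self):
        drift = np.linspace(0, 5, 2000)
        draws = np.column_stack([28 + drift, 1 + 0.01 * drift])
        report = effective_diagnostics(ParameterChain(draws, 0.5, ("P", "S")))
        assert report.flagged

    def test_short_chain_rejected(self):
        draws = np.zeros((50, 2))
        with pytest.raises(ValueError):
            effective_diagnostics(ParameterChain(draws, 0.5, ("P", "S")))


class TestConfigValidation:
    def test_bad_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(seed=1, n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(seed=1, thin=0)
        with pytest.raises(ValueError):
            PriorSpec(P_bounds=(35.0, 20.0))
        with pytest.raises(ValueError):
            PriorSpec(S_scale=-1.0)
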
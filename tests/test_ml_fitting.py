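import math

import numpy as np
import pytest

from tsdnorm.fmf_pipeline import split_limbs
from tsdnorm.ml_fitting import (
    BinomialDataset,
    SmallSampleError,
    aicc,
    akaike_weights,
    fit_mle,
    log_likelihood,
    select_model,
)
from tsdnorm.reaction_norms import LogisticNorm, flexit_sr, logistic_sr, FlexitNorm


def make_data(temps, males, totals):
    return BinomialDataset(np.asarray(temps, float), np.asarray(males, float),
                           np.asarray(totals, float))


def all_fixture_limbs(gekko):
    for pop in gekko.populations:
        _, fm, mf = split_limbs(gekko, pop)
        yield pop, "FM", fm
        yield pop, "MF", mf


class TestLikelihood:
    def test_single_point_value(self):
        data = make_data([28.0, 30.0], [1, 0], [2, 1])
        # sr(28) = 0.5 under a norm pivoting at 28; contribution 2 ln 0.5
        norm = LogisticNorm(28.0, 1e6)
        expected = 2 * math.log(0.5) + 1 * math.log(1 - logistic_sr(norm, 30.0))
        assert log_likelihood(norm, data) == pytest.approx(expected)

    def test_equals_per_individual_bernoulli_sum(self, gekko):
        """Grouped binomial log-likelihood equals the per-egg Bernoulli sum."""
        norm = LogisticNorm(27.0, 1.4)
        for _, direction, data in all_fixture_limbs(gekko):
            per_egg = 0.0
            for T, m, n in zip(data.temperatures, data.males, data.totals):
                p = logistic_sr(norm, T)
                per_egg += m * math.log(p) + (n - m) * math.log(1 - p)
            assert log_likelihood(norm, data) == pytest.approx(per_egg, rel=1e-12)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            make_data([24.0, 24.0], [1, 1], [2, 2])  # one distinct temperature
        with pytest.raises(ValueError):
            make_data([24.0, 26.0], [3, 0], [2, 2])  # males > totals


class TestAicc:
    def test_formula(self):
        assert aicc(-10.0, 2, 5) == pytest.approx(30.0)

    def test_approaches_aic_for_large_n(self):
        assert aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_small_sample_guard(self):
        with pytest.raises(SmallSampleError):
            aicc(-10.0, 2, 3)


class TestAkaikeWeights:
    def test_equal_scores_equal_weights(self):
        assert akaike_weights([12.0, 12.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_shift_invariance_and_normalisation(self):
        w1 = akaike_weights([3.0, 5.5, 9.1])
        w2 = akaike_weights([103.0, 105.5, 109.1])
        assert w1 == pytest.approx(w2)
        assert sum(w1) == pytest.approx(1.0, abs=1e-12)


class TestFitMle:
    def test_symmetric_counts_pin_the_midpoint(self):
        data = make_data([24.0, 28.0], [2, 8], [10, 10])
        fit = fit_mle(data, "logistic", "FM")
        assert fit.params.P == pytest.approx(26.0, abs=1e-3)
        assert fit.converged

    def test_beats_dense_grid_on_fixture_limbs(self, gekko):
        for _, direction, data in all_fixture_limbs(gekko):
            fit = fit_mle(data, "logistic", direction)
            sign = 1.0 if direction == "FM" else -1.0
            t_lo, t_hi = data.temperatures.min() - 5, data.temperatures.max() + 5
            best_grid = -np.inf
            for P in np.linspace(t_lo, t_hi, 80):
                for s in np.linspace(0.02, 5.0, 80):
                    ll = log_likelihood(LogisticNorm(P, sign * s), data)
                    best_grid = max(best_grid, ll)
            assert fit.logLik >= best_grid - 1e-6

    def test_degenerate_limb_flagged_not_raised(self):
        data = make_data([24.0, 26.0], [10, 12], [10, 12])  # all male
        fit = fit_mle(data, "logistic", "FM")
        assert not fit.converged

    def test_direction_constrains_sign(self):
        data = make_data([28.0, 30.0, 32.0], [44, 42, 10], [60, 71, 49])
        fit = fit_mle(data, "logistic", "MF")
        assert fit.params.S < 0

    def test_parameter_recovery_over_many_simulations(self):
        """Mean MLE pivot within 0.1 degC of truth, RMSE < 0.5, over 200 draws."""
        rng = np.random.default_rng(2016)
        truth = LogisticNorm(26.5, 1.5)
        temps = np.array([24.0, 26.0, 28.0, 30.0])
        estimates = []
        for _ in range(200):
            p = logistic_sr(truth, temps)
            males = rng.binomial(100, p)
            data = make_data(temps, males, [100] * 4)
            estimates.append(fit_mle(data, "logistic", "FM").params.P)
        estimates = np.asarray(estimates)
        assert abs(estimates.mean() - 26.5) < 0.1
        assert np.sqrt(np.mean((estimates - 26.5) ** 2)) < 0.5


class TestSelectModel:
    def test_logistic_truth_prefers_logistic(self):
        rng = np.random.default_rng(7)
        truth = LogisticNorm(27.0, 1.2)
        temps = np.array([24.0, 26.0, 28.0, 30.0, 32.0])
        males = rng.binomial(500, logistic_sr(truth, temps))
        sel = select_model(make_data(temps, males, [500] * 5), "FM")
        assert sel.best == "logistic"
        assert sel.delta_aicc["logistic"] == 0.0
        assert sum(sel.akaike_weight.values()) == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_flexit_truth_prefers_flexit(self):
        rng = np.random.default_rng(11)
        truth = FlexitNorm(27.0, 0.25, 10.0, 0.3)
        temps = np.array([24.0, 26.0, 28.0, 30.0, 32.0])
        males = rng.binomial(500, flexit_sr(truth, temps))
        sel = select_model(make_data(temps, males, [500] * 5), "FM")
        assert sel.best == "flexit"

    def test_small_limb_drops_flexit_with_warning(self):
        data = make_data([24.0, 26.0], [1, 2], [3, 2])  # n = 5 < k_flexit + 2
        with pytest.warns(UserWarning, match="flexit"):
            sel = select_model(data, "FM")
        assert sel.best == "logistic"
        assert sel.dropped == ("flexit",)
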
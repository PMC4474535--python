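"""Unit tests for the background-corrected signal model."""

import numpy as np
import pytest
from scipy import stats

from xbseq.model import (
    compute_size_factors,
    condition_moments,
    correct_signal,
    correct_variance,
    estimate_lambda,
    fit_mean_variance,
    fit_signal_model,
    nb_params,
)


class TestEstimateLambda:
    @pytest.mark.parametrize(
        "row,expected",
        [([20, 20, 28], 22.7), ([0, 0, 0], 0.0), ([64, 4, 64], 44.0)],
    )
    def test_per_gene_mean(self, row, expected):
        lam = estimate_lambda(np.array([row]), [0, 1, 2])
        assert round(float(lam[0]), 1) == expected

    def test_subset_selects_columns(self):
        B = np.array([[1, 2, 100, 200]])
        assert estimate_lambda(B, [0, 1])[0] == 1.5
        assert estimate_lambda(B, [2, 3])[0] == 150.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            estimate_lambda(np.array([[1, 2]]), [])


class TestCorrectSignal:
    @pytest.mark.parametrize(
        "x,b,expected",
        [
            ([63, 47, 77], [20, 20, 28], [43, 27, 49]),
            ([213, 88, 165], [216, 77, 142], [0, 11, 23]),
            ([5, 5], [5, 5], [0, 0]),
        ],
    )
    def test_per_replicate_subtraction_clamped(self, x, b, expected):
        out = correct_signal(np.array([x]), np.array([b]))
        assert out.tolist() == [expected]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correct_signal(np.zeros((2, 3)), np.zeros((2, 2)))

    def test_bounds_and_zero_background_identity(self, rng):
        X = rng.integers(0, 1000, size=(50, 4))
        B = rng.integers(0, 1000, size=(50, 4))
        S = correct_signal(X, B)
        assert (S >= 0).all() and (S <= X).all()
        assert np.array_equal(correct_signal(S, np.zeros_like(S)), S)


class TestSizeFactors:
    def test_identical_columns_are_unit(self):
        counts = np.array([[3, 3], [10, 10], [7, 7]])
        assert np.allclose(compute_size_factors(counts), [1.0, 1.0])

    def test_proportional_columns(self):
        counts = np.array([[10, 20], [20, 40], [30, 60]])
        assert np.allclose(
            compute_size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_single_gene(self):
        assert np.allclose(
            compute_size_factors(np.array([[4, 9]])), [2 / 3, 3 / 2]
        )

    def test_proportionality_property(self, rng):
        base = rng.integers(1, 500, size=(100, 1)).astype(float)
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        counts = base * scales[None, :]
        sf = compute_size_factors(counts)
        assert np.allclose(sf / sf[0], scales / scales[0])

    def test_zero_containing_genes_excluded(self):
        counts = np.array([[0, 100], [10, 10], [20, 20]])
        assert np.allclose(compute_size_factors(counts), [1.0, 1.0])

    def test_no_eligible_gene_is_error(self):
        with pytest.raises(ValueError, match="size factor"):
            compute_size_factors(np.array([[0, 1], [1, 0]]))


class TestConditionMoments:
    @pytest.mark.parametrize(
        "values,mean,sd",
        [
            ([43, 27, 49], 39.7, 11.4),
            ([42, 83, 87], 70.7, 24.9),
            ([5, 5, 5], 5.0, 0.0),
        ],
    )
    def test_mean_and_unbiased_sd(self, values, mean, sd):
        out = condition_moments(np.array([values], dtype=float), ["c"] * 3)
        assert round(float(out["c"]["mu"][0]), 1) == mean
        assert round(float(np.sqrt(out["c"]["var"][0])), 1) == sd

    def test_single_replicate_variance_undefined(self):
        out = condition_moments(np.array([[4.0, 7.0]]), ["a", "b"])
        assert np.isnan(out["a"]["var"][0]) and np.isnan(out["b"]["var"][0])
        assert out["a"]["m"] == 1


class TestMeanVarianceTrend:
    def test_recovers_poisson_like_trend(self, rng):
        mu = np.exp(rng.uniform(0.5, 7, size=400))
        var = mu * np.exp(rng.normal(0, 0.1, size=400))
        fit = fit_mean_variance(mu, var)
        q = np.exp(np.linspace(1.0, 6.5, 20))
        ratio = fit(q) / q
        assert (ratio > 0.8).all() and (ratio < 1.25).all()

    def test_recovers_quadratic_trend(self, rng):
        mu = np.exp(rng.uniform(0.5, 7, size=600))
        var = (mu + 0.1 * mu ** 2) * np.exp(rng.normal(0, 0.1, size=600))
        fit = fit_mean_variance(mu, var)
        assert abs(fit(np.array([100.0]))[0] - 1100) < 0.2 * 1100

    def test_clamped_outside_training_range(self, rng):
        mu = np.exp(rng.uniform(2, 5, size=200))
        var = mu * 2
        fit = fit_mean_variance(mu, var)
        low = fit(np.array([1e-6]))[0]
        at_boundary = fit(np.array([mu.min()]))[0]
        assert low == pytest.approx(at_boundary, rel=1e-9)

    def test_parametric_fallback_with_few_points(self, caplog):
        mu = np.array([10.0, 20.0, 40.0])
        var = mu + 0.05 * mu ** 2
        with caplog.at_level("WARNING"):
            fit = fit_mean_variance(mu, var)
        assert "parametric" in caplog.text
        assert fit(np.array([30.0]))[0] == pytest.approx(30 + 0.05 * 900, rel=0.2)

    def test_jensen_correction_calibrates_low_df_variances(self, rng):
        # 2-df sample variances of a known trend: the fitted trend must be
        # centred on the truth, not on the biased mean of log variances
        mu = np.exp(rng.uniform(2, 6, size=3000))
        true_var = mu + 0.1 * mu ** 2
        draws = rng.normal(mu[:, None], np.sqrt(true_var)[:, None], size=(3000, 3))
        var = draws.var(axis=1, ddof=1)
        fit = fit_mean_variance(mu, var, df=2)
        q = np.exp(np.linspace(2.5, 5.5, 10))
        ratio = fit(q) / (q + 0.1 * q ** 2)
        assert (np.abs(np.log(ratio)) < np.log(1.3)).all()


class TestVarianceCorrectionAndNBParams:
    def test_max_rule_and_floor(self):
        fitted = lambda q: np.full_like(np.asarray(q, dtype=float), 120.0)
        assert correct_variance(np.array([50.0]), np.array([50.0]), fitted)[0] == 120
        assert correct_variance(np.array([50.0]), np.array([200.0]), fitted)[0] == 200
        low = lambda q: np.full_like(np.asarray(q, dtype=float), 6.0)
        out = correct_variance(np.array([10.0]), np.array([4.0]), low)[0]
        assert out == pytest.approx(10 * (1 + 1e-8))

    def test_nb_params_worked_values(self):
        r, p, degen = nb_params(np.array([39.7]), np.array([129.33]))
        assert r[0] == pytest.approx(39.7 ** 2 / (129.33 - 39.7), rel=1e-12)
        assert p[0] == pytest.approx(39.7 / 129.33, rel=1e-12)
        assert not degen[0]
        # round trip: NB(r, p) has mean r(1-p)/p and variance mu/p
        assert r[0] * (1 - p[0]) / p[0] == pytest.approx(39.7)

    def test_degenerate_mean_zero(self):
        r, p, degen = nb_params(np.array([0.0]), np.array([0.0]))
        assert degen[0] and np.isnan(r[0])

    def test_poisson_limit(self):
        mu = 10.0
        r, p, _ = nb_params(np.array([mu]), np.array([mu * (1 + 1e-8)]))
        nb = stats.nbinom(r[0], p[0]).pmf(10)
        po = stats.poisson(mu).pmf(10)
        assert abs(nb - po) < 1e-4

    def test_moment_round_trip_grid(self):
        mus = np.array([0.5, 2.0, 10.0, 50.0, 400.0])
        vars_ = mus * np.array([1.5, 2.0, 3.0, 1.01, 10.0])
        r, p, degen = nb_params(mus, vars_)
        assert not degen.any()
        dist_mean = r * (1 - p) / p
        dist_var = dist_mean / p
        assert np.allclose(dist_mean, mus)
        assert np.allclose(dist_var, vars_)


def test_delaporte_moment_identities(rng):
    """Sample moments of NB + Poisson match lambda + alpha*beta and
    lambda + alpha*beta*(1 + beta) within 3 standard errors."""
    lam, alpha, beta = 22.7, 8.0, 5.0
    n = 100_000
    # NB with mean alpha*beta, variance alpha*beta*(1+beta):
    # scipy n=alpha, p=1/(1+beta)
    s = stats.nbinom(alpha, 1 / (1 + beta)).rvs(n, random_state=rng)
    b = stats.poisson(lam).rvs(n, random_state=rng)
    x = s + b
    mean_expected = lam + alpha * beta
    var_expected = lam + alpha * beta * (1 + beta)
    se_mean = x.std(ddof=1) / np.sqrt(n)
    m = x.mean()
    central4 = ((x - m) ** 4).mean()
    se_var = np.sqrt((central4 - x.var(ddof=1) ** 2) / n)
    assert abs(m - mean_expected) < 3 * se_mean
    assert abs(x.var(ddof=1) - var_expected) < 3 * se_var


def test_signal_model_on_worked_example(worked_example):
    sm = fit_signal_model(worked_example)
    assert sm.conditions == ["WT", "MYC"]
    expected_shat = {
        "Nat1": [43, 27, 49, 68, 96, 86],
        "Brca2": [0, 11, 23, 42, 83, 87],
        "Calcr": [0, 0, 0, 0, 0, 0],
        "Adh7": [203, 197, 107, 184, 378, 195],
    }
    for i, g in enumerate(sm.gene_ids):
        assert sm.s_hat[i].tolist() == expected_shat[g]
    assert round(float(sm.lam_by_condition["WT"][0]), 1) == 22.7
    assert round(float(sm.lam_by_condition["MYC"][2]), 1) == 203.3
    assert (sm.size_factors > 0).all()
    # corrected variance never below the per-condition mean
    for c in sm.conditions:
        assert (sm.var_corrected[c] >= sm.mu[c]).all()
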
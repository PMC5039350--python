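"""Design matrices, log-link rates, priors, posteriors and model restrictions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import norm

import bzipreg as bz
from bzipreg.regression import PriorSpec


def small_dataset(n=50, seed=0, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    names = ["intercept"] + [f"x{j}" for j in range(1, p)]
    params = bz.RegressionParams(
        beta=[0.3] + [0.2] * (p - 1), gamma=[-0.5] + [0.1] * (p - 1), alpha=-2.0, p0=0.35
    )
    y = bz.generate_responses(X, params, seed=seed + 1)
    return bz.BivariateCountDataset(y1=y[:, 0], y2=y[:, 1], X=X, covariate_names=names), params


class TestComputeRates:
    def test_zero_coefficients_give_unit_rates(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        params = bz.RegressionParams(beta=[0, 0], gamma=[0, 0], alpha=0.0, p0=0.5)
        lam1, lam2, lam3 = bz.compute_rates(X, params)
        np.testing.assert_allclose(lam1, 1.0)
        np.testing.assert_allclose(lam2, 1.0)
        assert lam3 == 1.0

    def test_intercept_only_log_link_inverse(self):
        X = np.ones((5, 1))
        params = bz.RegressionParams(
            beta=[math.log(2)], gamma=[math.log(3)], alpha=math.log(0.5), p0=0.4
        )
        lam1, lam2, lam3 = bz.compute_rates(X, params)
        np.testing.assert_allclose(lam1, 2.0, rtol=1e-14)
        np.testing.assert_allclose(lam2, 3.0, rtol=1e-14)
        assert lam3 == pytest.approx(0.5, rel=1e-14)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exp_dot_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 4))
        beta, gamma = rng.normal(size=4), rng.normal(size=4)
        params = bz.RegressionParams(beta=beta, gamma=gamma, alpha=rng.normal(), p0=0.5)
        lam1, lam2, lam3 = bz.compute_rates(X, params)
        for i in range(20):
            assert lam1[i] == pytest.approx(math.exp(np.dot(X[i], beta)), rel=1e-12)
            assert lam2[i] == pytest.approx(math.exp(np.dot(X[i], gamma)), rel=1e-12)
        assert lam3 == pytest.approx(math.exp(params.alpha), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        params = bz.RegressionParams(beta=[0, 0], gamma=[0, 0], alpha=0.0, p0=0.5)
        with pytest.raises(ValueError):
            bz.compute_rates(np.ones((3, 3)), params)

    def test_extreme_predictors_are_clipped_not_overflowed(self):
        X = np.full((2, 1), 1.0)
        params = bz.RegressionParams(beta=[800.0], gamma=[-800.0], alpha=0.0, p0=0.5)
        lam1, lam2, _ = bz.compute_rates(X, params)
        assert np.all(np.isfinite(lam1)) and np.all(lam2 > 0)


class TestLogLikelihood:
    def test_empty_dataset_gives_zero(self):
        data = bz.BivariateCountDataset(
            y1=np.array([], dtype=int), y2=np.array([], dtype=int),
            X=np.ones((0, 1)), covariate_names=["intercept"],
        )
        params = bz.RegressionParams(beta=[0.0], gamma=[0.0], alpha=0.0, p0=0.5)
        assert bz.log_likelihood(data, params) == 0.0

    def test_single_observation_equals_joint_pmf(self):
        data = bz.BivariateCountDataset(
            y1=[0], y2=[0], X=np.ones((1, 1)), covariate_names=["intercept"]
        )
        params = bz.RegressionParams(beta=[0.2], gamma=[-0.3], alpha=-1.0, p0=0.3)
        expected = bz.bzip_log_pmf(
            0, 0,
            bz.BZIPParamsCore(0.3, bz.BPRates(math.exp(0.2), math.exp(-0.3), math.exp(-1.0))),
        )
        assert bz.log_likelihood(data, params) == pytest.approx(expected, rel=1e-12)

    def test_equals_sum_of_per_row_joint_pmfs(self):
        data, params = small_dataset(n=50)
        lam1, lam2, lam3 = bz.compute_rates(data.X, params)
        expected = sum(
            bz.bzip_log_pmf(
                int(data.y1[i]), int(data.y2[i]),
                bz.BZIPParamsCore(params.p0, bz.BPRates(lam1[i], lam2[i], lam3)),
            )
            for i in range(data.n)
        )
        assert bz.log_likelihood(data, params) == pytest.approx(expected, rel=1e-10)

    def test_permutation_invariant(self):
        data, params = small_dataset(n=40, seed=3)
        perm = np.random.default_rng(5).permutation(data.n)
        shuffled = bz.BivariateCountDataset(
            y1=data.y1[perm], y2=data.y2[perm], X=data.X[perm], covariate_names=data.covariate_names
        )
        assert bz.log_likelihood(shuffled, params) == pytest.approx(
            bz.log_likelihood(data, params), rel=1e-12
        )

    def test_increasing_p0_hurts_data_without_joint_zeros(self):
        rng = np.random.default_rng(2)
        n = 30
        data = bz.BivariateCountDataset(
            y1=rng.poisson(3, n) + 1, y2=rng.poisson(1, n), X=np.ones((n, 1)),
            covariate_names=["intercept"],
        )
        lls = [
            bz.log_likelihood(
                data, bz.RegressionParams(beta=[1.0], gamma=[0.0], alpha=-2.0, p0=p0)
            )
            for p0 in (0.05, 0.2, 0.5, 0.8)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_matches_bp_as_p0_vanishes(self):
        data, params = small_dataset(n=30, seed=4)
        model = bz.restrict_model(data, "bp")
        theta_bp = np.concatenate([params.beta, params.gamma, [params.alpha]])
        tiny = bz.RegressionParams(
            beta=params.beta, gamma=params.gamma, alpha=params.alpha, p0=1e-12
        )
        assert bz.log_likelihood(data, tiny) == pytest.approx(
            model.log_likelihood_constrained(theta_bp), abs=1e-6
        )


class TestPriors:
    def test_density_at_mode_single_covariate(self):
        params = bz.RegressionParams(beta=[0.0], gamma=[0.0], alpha=0.0, p0=0.5)
        expected = 3 * norm.logpdf(0.0, 0.0, math.sqrt(1000.0))
        assert bz.log_prior(params) == pytest.approx(expected, rel=1e-12)

    def test_p0_outside_support_gives_minus_inf(self):
        params = bz.RegressionParams(beta=[0.0], gamma=[0.0], alpha=0.0, p0=0.5)
        params.p0 = 1.2  # mutate past construction-time validation
        assert bz.log_prior(params) == -math.inf

    @given(st.integers(0, 2**31 - 1))
    def test_matches_sum_of_log_densities_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = bz.RegressionParams(
            beta=rng.normal(size=3), gamma=rng.normal(size=3),
            alpha=float(rng.normal()), p0=float(rng.uniform(0.01, 0.99)),
        )
        sd = math.sqrt(1000.0)
        expected = sum(
            norm.logpdf(v, 0.0, sd)
            for v in [*params.beta, *params.gamma, params.alpha]
        )
        assert bz.log_prior(params) == pytest.approx(expected, rel=1e-12)

    def test_log_posterior_is_likelihood_plus_prior(self):
        data, params = small_dataset(n=25, seed=6)
        assert bz.log_posterior(data, params) == pytest.approx(
            bz.log_likelihood(data, params) + bz.log_prior(params), rel=1e-12
        )

    def test_log_posterior_minus_inf_outside_support(self):
        data, params = small_dataset(n=10, seed=7)
        setattr(params, "p0", 1.5)
        assert bz.log_posterior(data, params) == -math.inf

    def test_prior_term_cancels_in_flat_limit(self):
        data, params = small_dataset(n=25, seed=8)
        flat = PriorSpec(coef_variance=1e12)
        other = bz.RegressionParams(
            beta=params.beta + 0.1, gamma=params.gamma, alpha=params.alpha, p0=params.p0
        )
        dpost = bz.log_posterior(data, params, flat) - bz.log_posterior(data, other, flat)
        dlik = bz.log_likelihood(data, params) - bz.log_likelihood(data, other)
        assert dpost == pytest.approx(dlik, abs=1e-6)


class TestModelRestrictions:
    def test_bp_restriction_is_sum_of_bp_terms(self):
        data, params = small_dataset(n=30, seed=9)
        model = bz.restrict_model(data, "bp")
        theta = np.concatenate([params.beta, params.gamma, [params.alpha]])
        lam1, lam2, lam3 = bz.compute_rates(data.X, params)
        expected = sum(
            bz.bp_log_pmf(int(data.y1[i]), int(data.y2[i]), bz.BPRates(lam1[i], lam2[i], lam3))
            for i in range(data.n)
        )
        assert model.log_likelihood_constrained(theta) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("which", [1, 2])
    def test_poisson_restriction_closed_form(self, which):
        data, _ = small_dataset(n=20, seed=10)
        model = bz.restrict_model(data, f"poisson_y{which}")
        beta = np.array([0.4, -0.2, 0.1])
        lam = np.exp(data.X @ beta)
        y = data.y1 if which == 1 else data.y2
        expected = float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))
        assert model.log_likelihood_constrained(beta) == pytest.approx(expected, rel=1e-12)

    def test_zip_p0_concentrates_near_zero_without_zeros(self):
        # with no zeros in the response, the posterior of the zero-inflation
        # mass piles up near 0
        rng = np.random.default_rng(12)
        n = 200
        data = bz.BivariateCountDataset(
            y1=rng.poisson(4, n) + 1, y2=rng.poisson(1, n), X=np.ones((n, 1)),
            covariate_names=["intercept"],
        )
        model = bz.restrict_model(data, "zip_y1")
        samples = bz.run_chains(
            model, bz.ChainConfig(n_chains=2, burn_in=400, n_iter=800, thin=2, seed=3)
        )
        p0_draws = samples.parameter("p0")
        assert np.mean(p0_draws) < 0.05

    def test_unknown_family_rejected(self):
        data, _ = small_dataset(n=10)
        with pytest.raises(ValueError, match="unknown model family"):
            bz.restrict_model(data, "negative_binomial")

    def test_full_model_posterior_finite_on_random_cloud(self):
        data, _ = small_dataset(n=40, seed=13)
        model = bz.restrict_model(data, "bzip")
        rng = np.random.default_rng(14)
        for _ in range(50):
            z = rng.normal(scale=0.8, size=model.n_params)
            lp = model.log_posterior_unconstrained(z)
            assert math.isfinite(lp)


class TestDatasetHandling:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            bz.BivariateCountDataset(
                y1=[1, 2], y2=[1], X=np.ones((2, 1)), covariate_names=["intercept"]
            )
        with pytest.raises(ValueError):
            bz.BivariateCountDataset(
                y1=[-1], y2=[0], X=np.ones((1, 1)), covariate_names=["intercept"]
            )

    def test_both_zero_indicator_cached(self):
        data = bz.BivariateCountDataset(
            y1=[0, 1, 0], y2=[0, 0, 2], X=np.ones((3, 1)), covariate_names=["intercept"]
        )
        np.testing.assert_array_equal(data.both_zero, [True, False, False])

    def test_csv_roundtrip_with_categoricals_and_centering(self, tmp_path):
        df = pd.DataFrame(
            {
                "y1": [0, 1, 2, 0, 3, 0],
                "y2": [0, 0, 1, 0, 1, 0],
                "age": [30.0, 40.0, 50.0, 35.0, 45.0, 40.0],
                "job": ["housekeeper", "clerk", "worker", "clerk", "worker", "housekeeper"],
            }
        )
        path = tmp_path / "data.csv"
        df.to_csv(path, index=False)
        data = bz.load_dataset(
            path, categorical={"job": "housekeeper"}, center=["age"]
        )
        assert data.covariate_names == [
            "intercept", "age - mean(age)", "job[clerk vs housekeeper]",
            "job[worker vs housekeeper]",
        ]
        assert data.X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        # dummies are 0/1 and mutually exclusive
        dummies = data.X[:, 2:]
        assert set(np.unique(dummies)) <= {0.0, 1.0}
        assert np.all(dummies.sum(axis=1) <= 1)

    def test_reference_level_must_exist(self):
        df = pd.DataFrame({"y1": [0], "y2": [0], "job": ["worker"]})
        with pytest.raises(ValueError, match="reference level"):
            bz.load_dataset(df, categorical={"job": "manager"})
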
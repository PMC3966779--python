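"""Covariate detection model: recovery, prediction, prior derivation."""

import warnings

import numpy as np
import pytest
from scipy.special import expit

from occubound import (
    CovariateTable,
    DetectionModelPosterior,
    LogitDetectionSpec,
    MCMCConfig,
    SimulationParams,
    UnidentifiableDataError,
    derive_q_prior,
    fit_detection_model,
    predict_q,
    simulate_covariate_dataset,
)


def _fit(spec, T, seed, fit_seed, **mcmc_kw):
    params = SimulationParams(T=T, J=T, K=2, gamma=0.5, logit_spec=spec, seed=seed)
    ds = simulate_covariate_dataset(params)
    cov = CovariateTable(strata=ds.strata[ds.sampled], visibility=ds.visibility)
    kw = dict(n_iterations=3000, n_burnin=1500, seed=fit_seed)
    kw.update(mcmc_kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ds, cov, fit_detection_model(ds.y, cov, mcmc=MCMCConfig(**kw))


def test_intercept_recovery_on_large_survey():
    # truth: q = invlogit(0.4055) = 0.6, phi = invlogit(0) = 0.5
    spec = LogitDetectionSpec(a0=0.0, a1=0.0, b0=0.4055, b1=0.0)
    _, _, post = _fit(spec, T=2000, seed=11, fit_seed=5)
    assert abs(expit(post.b0).mean() - 0.6) < 0.05
    assert abs(expit(post.a0).mean() - 0.5) < 0.05


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_strata_coefficient_recovery(seed):
    spec = LogitDetectionSpec(a0=0.5, a1=-1.0, b0=0.4055, b1=0.0)
    _, _, post = _fit(spec, T=1500, seed=seed, fit_seed=seed + 1)
    assert abs(post.a1.mean() - (-1.0)) < 0.3


def test_no_visibility_effect_centers_on_zero():
    # identical detection frequencies in both visibility classes by
    # construction: visibility alternates and detections mirror it
    J = 400
    strata = np.zeros(J, dtype=np.int8)
    vis = np.tile([[0, 1]], (J, 1)).astype(np.int8)
    y = np.zeros((J, 2), dtype=np.int8)
    y[: J // 2, 0] = 1  # half detected in the good-visibility pass
    y[: J // 2, 1] = 1  # ... and the same half in the poor-visibility pass
    cov = CovariateTable(strata=strata, visibility=vis)
    post = fit_detection_model(
        y, cov, mcmc=MCMCConfig(seed=9, n_iterations=3000, n_burnin=1500)
    )
    b1 = post.b1
    assert abs(b1.mean()) < 2 * b1.std(ddof=1)


def test_zero_detections_unidentifiable():
    cov = CovariateTable(
        strata=np.zeros(10, dtype=np.int8), visibility=np.zeros((10, 2), dtype=np.int8)
    )
    with pytest.raises(UnidentifiableDataError, match="conditional occupancy"):
        fit_detection_model(np.zeros((10, 2), dtype=np.int8), cov)


def test_complete_separation_warns():
    rng = np.random.default_rng(0)
    J = 60
    vis = rng.integers(0, 2, size=(J, 2)).astype(np.int8)
    y = ((vis == 0) & (rng.random((J, 2)) < 0.8)).astype(np.int8)  # only good-vis detections
    assert y.sum() > 0
    cov = CovariateTable(strata=np.zeros(J, dtype=np.int8), visibility=vis)
    with pytest.warns(UserWarning, match="separation"):
        fit_detection_model(
            y, cov, mcmc=MCMCConfig(seed=1, n_iterations=200, n_burnin=100)
        )


class TestPredictQ:
    def _point_posterior(self, b0, b1, n=100):
        z = np.zeros(n)
        return DetectionModelPosterior(
            a0=z, a1=z, b0=np.full(n, b0), b1=np.full(n, b1)
        )

    def test_null_coefficients_give_half(self):
        post = self._point_posterior(0.0, 0.0)
        cov = CovariateTable(
            strata=np.zeros(4, dtype=np.int8),
            visibility=np.array([[0, 1]] * 4, dtype=np.int8),
        )
        pred = predict_q(post, cov)
        assert np.allclose(pred.q_draws, 0.5)
        assert pred.region_mean() == pytest.approx(0.5)

    def test_visibility_split_region_mean(self):
        # half the plot-surveys poor visibility: mean = (invlogit(0)+invlogit(-1))/2
        post = self._point_posterior(0.0, -1.0)
        cov = CovariateTable(
            strata=np.zeros(10, dtype=np.int8),
            visibility=np.array([[0, 1]] * 10, dtype=np.int8),
        )
        pred = predict_q(post, cov)
        assert pred.region_mean() == pytest.approx((0.5 + expit(-1.0)) / 2, abs=1e-12)

    def test_homogeneous_visibility_mean_is_intercept(self):
        post = self._point_posterior(0.7, -1.0)
        cov = CovariateTable(
            strata=np.zeros(6, dtype=np.int8),
            visibility=np.zeros((6, 2), dtype=np.int8),
        )
        pred = predict_q(post, cov)
        assert pred.region_mean() == pytest.approx(float(expit(0.7)), abs=1e-12)

    def test_negative_visibility_effect_monotone_in_every_draw(self):
        rng = np.random.default_rng(3)
        n = 200
        post = DetectionModelPosterior(
            a0=np.zeros(n), a1=np.zeros(n),
            b0=rng.normal(0, 1, n), b1=-np.abs(rng.normal(1, 0.3, n)),
        )
        cov = CovariateTable(
            strata=np.zeros(2, dtype=np.int8),
            visibility=np.array([[0, 1], [0, 1]], dtype=np.int8),
        )
        pred = predict_q(post, cov)
        assert (pred.q_draws[:, :, 1] < pred.q_draws[:, :, 0]).all()


class TestDeriveQPrior:
    def test_constant_draws_become_point_mass(self):
        prior = derive_q_prior(np.full(500, 0.5))
        assert prior.is_point and prior.value == pytest.approx(0.5)

    def test_moment_matching_algebra(self):
        # mean 0.5, variance 1/20 matches Beta(2, 2) exactly
        rng = np.random.default_rng(1)
        draws = rng.beta(2, 2, 400_000)
        prior = derive_q_prior(draws)
        assert not prior.is_point
        assert prior.a == pytest.approx(2.0, abs=0.05)
        assert prior.b == pytest.approx(2.0, abs=0.05)

    def test_round_trip_moments(self):
        rng = np.random.default_rng(2)
        draws = rng.beta(8, 3, 5000)
        prior = derive_q_prior(draws)
        m, v = draws.mean(), draws.var(ddof=1)
        a, b = prior.a, prior.b
        assert a / (a + b) == pytest.approx(m, abs=1e-10)
        assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(v, abs=1e-10)

    def test_overdispersed_draws_fall_back_to_point_mass(self):
        # 4 extreme draws: the ddof=1 variance exceeds the Beta bound m(1-m)
        draws = np.array([0.001, 0.999, 0.001, 0.999])
        with pytest.warns(UserWarning, match="point mass"):
            prior = derive_q_prior(draws)
        assert prior.is_point and prior.value == pytest.approx(0.5)
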
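"""Conditional occupancy estimator: analytic oracles, enumeration, invariants."""

import itertools

import numpy as np
import pytest

from occubound import (
    DetectionHistorySet,
    DetectionPriorQ,
    MCMCConfig,
    brute_force_posterior,
    fit_conditional_occupancy,
    occupied_sites_upper,
)

# analytic mean of the conditioned Uniform prior at T = 10, J = 0:
# density ∝ 1 - (1-g)^10, mean = (1/2 - 1/132) / (10/11)
CONDITIONED_PRIOR_MEAN_T10 = (0.5 - 1.0 / 132.0) / (10.0 / 11.0)


def _enumeration_posterior(y, T, q, n_grid=4001):
    """Test-local oracle: sum the conditioned likelihood over all 2^T configs."""
    J, K = y.shape
    grid = (np.arange(n_grid) + 0.5) / n_grid
    gamma_w = np.zeros(n_grid)
    mass_x = {}
    for z in itertools.product((0, 1), repeat=T):
        x = sum(z)
        if x == 0:
            continue
        lik = np.ones(n_grid)
        for j in range(J):
            if z[j] == 1:
                lik *= np.prod(q ** y[j] * (1 - q) ** (1 - y[j]))
            elif y[j].any():
                lik *= 0.0
        w = grid**x * (1 - grid) ** (T - x) * lik
        gamma_w += w
        mass_x[x] = mass_x.get(x, 0.0) + w.sum()
    total = gamma_w.sum()
    xs = np.array(sorted(mass_x))
    px = np.array([mass_x[x] for x in xs])
    return grid, gamma_w / total, xs, px / px.sum()


class TestBruteForceGrid:
    def test_conditioned_prior_mean_with_no_sampling(self):
        hist = DetectionHistorySet.all_zero(T=10, J=0, K=2)
        grid = brute_force_posterior(hist, q=0.5)
        assert grid.gamma_mean() == pytest.approx(CONDITIONED_PRIOR_MEAN_T10, abs=1e-5)

    def test_matches_full_enumeration_over_z(self):
        # independent oracle: explicit sum over all 2^6 occupancy vectors
        y = np.array([[1, 0], [0, 0], [0, 0]], dtype=np.int8)
        hist = DetectionHistorySet(T=6, J=3, K=2, y=y)
        grid = brute_force_posterior(hist, q=0.6, n_grid=4001)
        g, w, xs, px = _enumeration_posterior(y, T=6, q=0.6)
        mean_enum = float((g * w).sum())
        assert grid.gamma_mean() == pytest.approx(mean_enum, abs=1e-6)
        np.testing.assert_allclose(grid.x_weights[xs], px, atol=1e-9)
        cdf = np.cumsum(w) - 0.5 * w  # midpoint-rule CDF at the nodes
        probe = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(
            grid.gamma_cdf(probe), np.interp(probe, g, cdf), atol=1e-6
        )

    def test_grid_refinement_converged(self):
        hist = DetectionHistorySet.all_zero(T=10, J=5, K=2)
        coarse = brute_force_posterior(hist, q=0.5, n_grid=2001)
        fine = brute_force_posterior(hist, q=0.5, n_grid=4002)
        assert abs(coarse.gamma_mean() - fine.gamma_mean()) < 1e-4

    def test_single_plot_detection_forces_occupancy(self):
        hist = DetectionHistorySet(T=1, J=1, K=1, y=np.array([[1]]))
        grid = brute_force_posterior(hist, q=0.5)
        assert grid.x_weights[1] == pytest.approx(1.0)
        assert grid.x_frac_mean() == pytest.approx(1.0)


class TestGibbsSampler:
    def test_conditioned_prior_mean_recovered(self):
        hist = DetectionHistorySet.all_zero(T=10, J=0, K=2)
        occ = fit_conditional_occupancy(
            hist,
            DetectionPriorQ.point(0.5),
            mcmc=MCMCConfig(seed=1, n_iterations=8000, n_burnin=1000),
        )
        assert occ.mean("gamma") == pytest.approx(CONDITIONED_PRIOR_MEAN_T10, abs=0.01)

    def test_posterior_mean_agrees_with_grid(self):
        hist = DetectionHistorySet.all_zero(T=10, J=5, K=2)
        grid = brute_force_posterior(hist, q=0.5)
        occ = fit_conditional_occupancy(
            hist,
            DetectionPriorQ.point(0.5),
            mcmc=MCMCConfig(seed=2, n_iterations=8000, n_burnin=1000),
        )
        assert occ.mean("gamma") == pytest.approx(grid.gamma_mean(), abs=0.01)

    def test_realized_fraction_floor_under_conditioning(self):
        hist = DetectionHistorySet.all_zero(T=25, J=12, K=2)
        occ = fit_conditional_occupancy(
            hist,
            DetectionPriorQ.point(0.7),
            mcmc=MCMCConfig(seed=3, n_iterations=4000, n_burnin=500),
        )
        assert occ.x_frac.min() >= 1.0 / 25 - 1e-12
        assert np.quantile(occ.x_frac, 0.025) >= 1.0 / 25 - 1e-12

    def test_single_detected_plot_point_mass(self):
        hist = DetectionHistorySet(T=1, J=1, K=1, y=np.array([[1]]))
        occ = fit_conditional_occupancy(
            hist,
            DetectionPriorQ.point(0.5),
            mcmc=MCMCConfig(seed=4, n_iterations=2000, n_burnin=200),
        )
        assert (occ.x_frac == 1.0).all()

    def test_beta_detection_prior_propagates(self):
        hist = DetectionHistorySet.all_zero(T=100, J=40, K=2)
        occ = fit_conditional_occupancy(
            hist,
            DetectionPriorQ.beta(20, 10),
            mcmc=MCMCConfig(seed=5, n_iterations=4000, n_burnin=500),
        )
        # q draws wander around the prior (no detection information at
        # mostly-unoccupied plots pulls weakly); all draws stay in (0,1)
        assert 0 < occ.q.min() and occ.q.max() < 1
        assert occ.q.std() > 0.01

    def test_perfect_detection_with_mixed_histories_is_valid(self):
        y = np.array([[1], [0]], dtype=np.int8)
        hist = DetectionHistorySet(T=5, J=2, K=1, y=y)
        occ = fit_conditional_occupancy(
            hist,
            DetectionPriorQ.point(1.0),
            mcmc=MCMCConfig(seed=6, n_iterations=2000, n_burnin=200),
        )
        # the non-detected plot can never be occupied under q = 1
        assert occ.x_frac.min() >= 1.0 / 5 - 1e-12

    def test_perfect_detection_full_census_zero_detections_impossible(self):
        hist = DetectionHistorySet.all_zero(T=4, J=4, K=1)
        with pytest.raises(ValueError, match="impossible"):
            fit_conditional_occupancy(
                hist,
                DetectionPriorQ.point(1.0),
                mcmc=MCMCConfig(seed=7, n_iterations=500, n_burnin=100),
            )

    def test_upper_quantile_non_increasing_in_detection_prior(self):
        # stronger detection + no sightings = stronger absence evidence;
        # checked on the exact grid posterior so the ordering is noise-free
        hist = DetectionHistorySet.all_zero(T=100, J=50, K=2)
        uppers = [
            brute_force_posterior(hist, q=q).gamma_quantile(0.975)
            for q in (0.2, 0.5, 0.8)
        ]
        assert uppers[0] >= uppers[1] >= uppers[2]


class TestOccupiedSitesUpper:
    @pytest.mark.parametrize(
        "g95u, T, expected",
        [
            (0.024, 1006, 24),  # floor of 24.144
            (1.0, 50, 50),
            (0.0001, 100, 1),  # presence floor
            (0.08, 400, 32),
            (0.1, 50, 5),  # exact product stays exact under the floor
        ],
    )
    def test_k_derivation(self, g95u, T, expected):
        assert occupied_sites_upper(g95u, T) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            occupied_sites_upper(1.2, 100)
        with pytest.raises(ValueError):
            occupied_sites_upper(0.5, 0)
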
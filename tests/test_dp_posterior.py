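"""Dirichlet-process posterior: Kaplan-Meier, partition, Gibbs sampler."""

import numpy as np
import pytest
from scipy import stats

from survassure import (
    DPPrior,
    PriorSpec,
    QuadratureGrid,
    SurvivalDataset,
    TrialDesign,
    assurance_ph_with_data,
    build_partition,
    kaplan_meier,
    posterior_survivor_draws,
)
from survassure.dp_posterior import gibbs_impute_censored, gibbs_update_p


@pytest.fixture
def dp_prior():
    # exponential shape anchored at S(5) = 0.5, weak precision
    return DPPrior.exponential_anchor(1.0, 5.0, 0.5)


class TestKaplanMeier:
    def test_example_data_survival_at_seven_months(self, km_data):
        km = kaplan_meier(km_data)
        assert km(7.0) == pytest.approx(0.525, abs=1e-9)

    def test_no_censoring_is_one_minus_ecdf(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        km = kaplan_meier(SurvivalDataset(times, np.ones(4)))
        assert km(2.5) == pytest.approx(0.5)
        assert km(0.5) == pytest.approx(1.0)
        assert km(5.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier(SurvivalDataset(np.array([1.0, 2.0, 3.0]), np.zeros(3)))
        assert km(10.0) == pytest.approx(1.0)

    def test_step_function_is_right_continuous(self, km_data):
        km = kaplan_meier(km_data)
        assert km(5.4) == pytest.approx(0.525)
        assert km(5.4 - 1e-9) == pytest.approx(0.7)


class TestPartition:
    def test_example_configuration_counts(self, km_data):
        grid = QuadratureGrid(5.0, 10.0, 11)
        part = build_partition(grid, km_data)
        # 11 nodes + 4 distinct censoring times, minus one merge: the
        # censoring time 7.0 coincides with a quadrature node
        assert len(part.cuts) == 14
        assert part.n_intervals == 15
        assert part.d.sum() == 4 and part.r.sum() == 4

    def test_no_censoring_uses_grid_nodes_only(self):
        data = SurvivalDataset(np.array([5.2, 6.1]), np.ones(2))
        grid = QuadratureGrid(5.0, 10.0, 5)
        part = build_partition(grid, data)
        assert np.allclose(part.cuts, grid.nodes)

    def test_censoring_time_equal_to_node_merged(self):
        data = SurvivalDataset(np.array([7.5, 8.0]), np.array([0, 1]))
        grid = QuadratureGrid(5.0, 10.0, 5)  # nodes 5, 6.25, 7.5, 8.75, 10
        part = build_partition(grid, data)
        assert len(part.cuts) == 5
        assert part.r.sum() == 1 and part.d.sum() == 1

    def test_record_interval_mapping(self, km_data):
        grid = QuadratureGrid(5.0, 10.0, 11)
        part = build_partition(grid, km_data)
        # event at 0.8 lands in the first interval (0, 1.0]
        assert part.d[0] == 1
        # censored at 12.1 lands in the last bounded interval (10, 12.1]
        assert part.r[-2] == 1


class TestGibbsSteps:
    def test_no_censoring_leaves_counts_unchanged(self, dp_prior):
        data = SurvivalDataset(np.array([5.5, 6.5, 7.5]), np.ones(3))
        part = build_partition(QuadratureGrid(5, 10, 5), data)
        p = np.full(part.n_intervals, 1 / part.n_intervals)
        _, d_prime = gibbs_impute_censored(p, part, 0)
        assert np.array_equal(d_prime, part.d)

    def test_uniform_mass_allocates_censored_record_uniformly(self):
        data = SurvivalDataset(np.array([5.5]), np.array([0]))
        part = build_partition(QuadratureGrid(5, 10, 5), data)
        k = int(part.interval_index(5.5))
        later = part.n_intervals - (k + 1)
        p = np.full(part.n_intervals, 1 / part.n_intervals)
        rng = np.random.default_rng(7)
        counts = np.zeros(part.n_intervals)
        n_rep = 20000
        for _ in range(n_rep):
            z, _ = gibbs_impute_censored(p, part, rng)
            counts += z[:, k]
        freq = counts[k + 1 :] / n_rep
        assert np.allclose(freq, 1 / later, atol=0.01)

    def test_imputation_conserves_record_count(self, km_data, dp_prior):
        part = build_partition(QuadratureGrid(5, 10, 11), km_data)
        rng = np.random.default_rng(3)
        alphas = dp_prior.alphas(part)
        p = alphas / alphas.sum()
        for _ in range(200):
            _, d_prime = gibbs_impute_censored(p, part, rng)
            assert d_prime.sum() == km_data.n
            p = gibbs_update_p(d_prime, alphas, rng)

    def test_dirichlet_prior_mean_without_data(self, dp_prior, km_data):
        part = build_partition(QuadratureGrid(5, 10, 11), km_data)
        alphas = dp_prior.alphas(part)
        rng = np.random.default_rng(5)
        draws = np.array([gibbs_update_p(np.zeros_like(alphas), alphas, rng) for _ in range(20000)])
        assert np.allclose(draws.mean(0), alphas / alphas.sum(), atol=0.01)

    def test_gibbs_matches_direct_conjugate_posterior_when_uncensored(self, dp_prior):
        """With no censoring the sampler is a plain Dirichlet draw; its
        marginals must match the closed-form conjugate posterior."""
        times = np.array([5.2, 5.7, 6.3, 6.9, 7.4, 8.1, 8.8, 9.4, 4.0, 6.0, 7.0, 9.0])
        data = SurvivalDataset(times, np.ones(len(times)))
        grid = QuadratureGrid(5, 10, 7)
        part = build_partition(grid, data)
        alphas = dp_prior.alphas(part)
        rng = np.random.default_rng(5)
        n = 20000
        gibbs = np.empty((n, part.n_intervals))
        p = alphas / alphas.sum()
        for i in range(n):
            _, d_prime = gibbs_impute_censored(p, part, rng)
            p = gibbs_update_p(d_prime, alphas, rng)
            gibbs[i] = p
        direct = rng.dirichlet(alphas + part.d, n)
        for node in grid.nodes[[1, 3, 5]]:
            k = int(np.searchsorted(part.cuts, node))
            s_gibbs = 1 - np.cumsum(gibbs, axis=1)[:, k]
            s_direct = 1 - np.cumsum(direct, axis=1)[:, k]
            assert stats.ks_2samp(s_gibbs, s_direct).statistic < 0.02


class TestPosteriorDraws:
    def test_weak_prior_posterior_tracks_kaplan_meier(self, km_data, dp_prior):
        grid = QuadratureGrid(5, 10, 11)
        draws = posterior_survivor_draws(
            km_data, dp_prior, grid, 7.0, n_iter=6000, burn_in=1000, rng_seed=2
        )
        assert draws.t0_samples.mean() == pytest.approx(0.525, abs=0.1)

    def test_huge_precision_recovers_prior_shape(self, km_data):
        prior = DPPrior.exponential_anchor(1e6, 5.0, 0.5)
        grid = QuadratureGrid(5, 10, 11)
        draws = posterior_survivor_draws(
            km_data, prior, grid, 7.0, n_iter=2000, burn_in=500, rng_seed=4
        )
        rate = np.log(2) / 5
        assert np.allclose(draws.node_means(), np.exp(-rate * grid.nodes), atol=0.01)

    def test_draws_monotone_and_in_unit_interval(self, km_data, dp_prior):
        grid = QuadratureGrid(5, 10, 11)
        draws = posterior_survivor_draws(
            km_data, dp_prior, grid, 7.0, n_iter=1500, burn_in=500, rng_seed=6
        )
        assert np.all(draws.node_samples >= 0) and np.all(draws.node_samples <= 1)
        assert np.all(np.diff(draws.node_samples, axis=1) <= 1e-12)

    def test_posterior_means_stable_across_seeds(self, km_data, dp_prior):
        grid = QuadratureGrid(5, 10, 11)
        a = posterior_survivor_draws(km_data, dp_prior, grid, 7.0, 6000, 1000, rng_seed=1)
        b = posterior_survivor_draws(km_data, dp_prior, grid, 7.0, 6000, 1000, rng_seed=2)
        se = a.t0_samples.std() / np.sqrt(200)  # generous effective-sample allowance
        assert abs(a.t0_samples.mean() - b.t0_samples.mean()) < 3 * se

    def test_anchor_time_outside_grid_is_covered(self, km_data, dp_prior):
        grid = QuadratureGrid(5, 10, 11)
        draws = posterior_survivor_draws(
            km_data, dp_prior, grid, 3.0, n_iter=1500, burn_in=500, rng_seed=8
        )
        assert np.all(draws.t0_samples >= draws.node_samples[:, 0] - 1e-12)


class TestAssuranceWithData:
    def test_zero_difference_prior_gives_half_alpha(self, km_data, dp_prior, design_10mo, grid_10mo):
        draws = posterior_survivor_draws(
            km_data, dp_prior, grid_10mo, 7.0, n_iter=2000, burn_in=500, rng_seed=3
        )
        res = assurance_ph_with_data(
            draws, PriorSpec("point", (0.0,)), design_10mo, grid_10mo, rng_seed=5
        )
        assert res.estimate == pytest.approx(design_10mo.alpha / 2, abs=1e-6)

    def test_large_trial_plateaus_below_prior_superiority(self, km_data, dp_prior, grid_10mo):
        draws = posterior_survivor_draws(
            km_data, dp_prior, grid_10mo, 7.0, n_iter=6000, burn_in=1000, rng_seed=3
        )
        rho = PriorSpec("normal", (0.175, 0.01))
        big = TrialDesign.balanced(5, 10, 2000)
        res = assurance_ph_with_data(draws, rho, big, grid_10mo, rng_seed=7)
        assert 0.90 < res.estimate < 0.97
        assert res.estimate <= res.prior_superiority + 3 * res.se

    def test_tight_treatment_prior_tracks_power_curve(self, km_data, dp_prior, design_10mo, grid_10mo):
        """Tightening the treatment-effect prior pulls the assurance curve
        toward the power curve at every sample size; residual deviation comes
        from the survivor-function posterior (only 8 historical records)."""
        from survassure import power_logrank, theta_from_rates, event_probabilities

        draws = posterior_survivor_draws(
            km_data, dp_prior, grid_10mo, 7.0, n_iter=6000, burn_in=1000, rng_seed=3
        )
        tight = PriorSpec("normal", (0.175, 0.001))
        diffuse = PriorSpec("normal", (0.175, 0.01))
        km = kaplan_meier(km_data)
        theta = theta_from_rates(0.525, 0.175)
        _, _, pe = event_probabilities(km(grid_10mo.nodes), theta, design_10mo, grid_10mo)
        gaps = {"tight": [], "diffuse": []}
        for n in (60, 100, 150):
            d = design_10mo.with_per_group(n)
            power = power_logrank(d.n_total, theta, pe, d)
            for name, prior in (("tight", tight), ("diffuse", diffuse)):
                res = assurance_ph_with_data(draws, prior, d, grid_10mo, rng_seed=9)
                gaps[name].append(abs(res.estimate - power))
            if 0.7 < power < 0.95:
                assert gaps["tight"][-1] < 0.05
        assert max(gaps["tight"]) < max(gaps["diffuse"])
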
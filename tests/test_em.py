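"""EM machinery: oracle equivalences, monotonicity, identities, recovery."""

import warnings

import numpy as np
import pytest
from scipy.stats import norm

from tetraqtl import (
    EMOptions,
    SimulationConfig,
    constraint_design,
    fit,
    fit_constrained,
    simulate_dataset,
)
from tetraqtl.em import (
    e_step,
    log_likelihood,
    log_likelihood_joint,
    m_step_g,
    m_step_means,
    m_step_rates,
    m_step_variance,
    recombination_count_rows,
)
from tetraqtl.gametes import (
    MODE_INDEX,
    build_joint_table,
    chromatid_modes,
)
from tetraqtl.quantgen import effects_to_means
from tetraqtl.simulate import BackcrossDataset, construct_g

FAST = EMOptions(r_grid_step=0.1, refine_points=3, tol=1e-5, max_iter=200)


def random_instance(rng, n=15):
    """Tiny random dataset plus random valid parameters for oracle checks."""
    g = chromatid_modes(rng.uniform(0.1, 0.4), rng.uniform(0.02, 0.4))
    marker = rng.integers(0, 10, size=n)
    y = rng.normal(size=n)
    means = rng.normal(size=10)
    sigma2 = rng.uniform(0.5, 2.0)
    return BackcrossDataset(marker=marker, phenotype=y), g, means, sigma2


class TestEStepOracle:
    def test_matches_direct_bayes_rule(self, rng):
        for _ in range(5):
            data, g, means, sigma2 = random_instance(rng)
            theta = e_step(data, g, means, sigma2)
            joint = build_joint_table(g)
            for i in range(data.n):
                row = joint[data.marker[i]]
                prior = row / row.sum()
                lik = norm.pdf(data.phenotype[i], means, np.sqrt(sigma2))
                expected = prior * lik / (prior * lik).sum()
                assert np.allclose(theta[i], expected, atol=1e-12)

    def test_posterior_zero_where_prior_zero(self, rng):
        g = np.zeros(9)
        g[0], g[6] = 0.3, 0.7  # only g1 and g7 modes populated
        data = BackcrossDataset(marker=np.array([0, 4]),
                                phenotype=np.array([0.0, 1.0]))
        theta = e_step(data, g, np.zeros(10), 1.0)
        joint = build_joint_table(g)
        assert np.all(theta[joint[data.marker] == 0] == 0)

    def test_equal_means_returns_prior(self, rng):
        data, g, _, sigma2 = random_instance(rng)
        theta = e_step(data, g, np.zeros(10), sigma2)
        joint = build_joint_table(g)
        prior = joint[data.marker] / joint[data.marker].sum(axis=1, keepdims=True)
        assert np.allclose(theta, prior, atol=1e-12)


class TestMStepOracles:
    def test_g_update_matches_layout_accumulation(self, rng):
        data, g, means, sigma2 = random_instance(rng, n=20)
        theta = e_step(data, g, means, sigma2)
        g_hat = m_step_g(data, theta)
        expected = np.zeros(9)
        for i in range(data.n):
            for j in range(10):
                expected[MODE_INDEX[data.marker[i], j]] += theta[i, j]
        assert np.allclose(g_hat, expected / data.n, atol=1e-12)
        assert g_hat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_g_update_complete_data_point_mass(self):
        data = BackcrossDataset(marker=np.zeros(8, dtype=int),
                                phenotype=np.zeros(8))
        theta = np.zeros((8, 10))
        theta[:, 0] = 1.0  # everyone in cell (M1M1, Q1Q1) -> mode g1
        assert m_step_g(data, theta)[0] == pytest.approx(1.0)

    def test_means_update_weighted_oracle(self, rng):
        data, g, means, sigma2 = random_instance(rng, n=20)
        theta = e_step(data, g, means, sigma2)
        m_hat = m_step_means(data, theta)
        w = theta.sum(axis=0)
        expected = np.where(w > 0, theta.T @ data.phenotype / np.maximum(w, 1e-300),
                            data.phenotype.mean())
        assert np.allclose(m_hat[w > 0], expected[w > 0], atol=1e-12)

    def test_hard_posteriors_give_group_means(self):
        y = np.array([1.0, 2.0, 5.0, 7.0])
        data = BackcrossDataset(marker=np.array([4, 4, 5, 5]), phenotype=y)
        theta = np.zeros((4, 10))
        theta[[0, 1], 4] = 1.0
        theta[[2, 3], 5] = 1.0
        m_hat = m_step_means(data, theta)
        assert m_hat[4] == pytest.approx(1.5)
        assert m_hat[5] == pytest.approx(6.0)

    def test_variance_update_oracle(self, rng):
        data, g, means, sigma2 = random_instance(rng, n=20)
        theta = e_step(data, g, means, sigma2)
        m_hat = m_step_means(data, theta)
        s2 = m_step_variance(data, theta, m_hat)
        expected = float((theta * (data.phenotype[:, None] - m_hat) ** 2).sum()
                         / data.n)
        assert s2 == pytest.approx(expected, abs=1e-12)

    def test_variance_floor(self):
        data = BackcrossDataset(marker=np.array([4, 4]),
                                phenotype=np.array([1.0, 1.0]))
        theta = np.zeros((2, 10))
        theta[:, 4] = 1.0
        assert m_step_variance(data, theta, np.ones(10), floor=0.123) == 0.123

    def test_rates_point_mass_and_round_trip(self):
        g = np.zeros(9)
        g[0] = 1.0
        assert m_step_rates(g) == pytest.approx((1.0, 1.0, 0.0))
        g = construct_g(0.15, 0.15, 0.25)
        a, b, r = m_step_rates(g)
        assert (a, b, r) == pytest.approx((0.15, 0.15, 0.25), abs=1e-8)


class TestLogLikelihood:
    def test_brute_force_oracle(self, rng):
        for _ in range(3):
            data, g, means, sigma2 = random_instance(rng)
            ll = log_likelihood(data, g, means, sigma2)
            joint = build_joint_table(g)
            expected = 0.0
            for i in range(data.n):
                row = joint[data.marker[i]]
                prior = row / row.sum()
                expected += np.log((prior * norm.pdf(
                    data.phenotype[i], means, np.sqrt(sigma2))).sum())
            assert ll == pytest.approx(expected, abs=1e-9)

    def test_point_mass_prior_is_normal_logpdf(self):
        g = np.zeros(9)
        g[0] = 1.0
        data = BackcrossDataset(marker=np.array([0]), phenotype=np.array([1.3]))
        means = np.arange(10.0)
        ll = log_likelihood(data, g, means, 2.0)
        assert ll == pytest.approx(norm.logpdf(1.3, 0.0, np.sqrt(2.0)), abs=1e-9)

    def test_doubling_data_doubles_loglik(self, rng):
        data, g, means, sigma2 = random_instance(rng)
        doubled = BackcrossDataset(
            marker=np.concatenate([data.marker, data.marker]),
            phenotype=np.concatenate([data.phenotype, data.phenotype]))
        assert log_likelihood(doubled, g, means, sigma2) == pytest.approx(
            2 * log_likelihood(data, g, means, sigma2), rel=1e-12)


class TestMonotonicity:
    def test_free_mode_joint_em_is_monotone(self, small_dataset):
        """The classic EM (free mode frequencies) never decreases the joint
        marker+phenotype log-likelihood."""
        data = small_dataset
        g = chromatid_modes(0.3, 0.25)
        g = 0.98 * g + 0.02 / 9
        means = np.linspace(-1, 3, 10)
        sigma2 = float(np.var(data.phenotype))
        r_prev = 0.25
        last = -np.inf
        for _ in range(60):
            theta = e_step(data, g, means, sigma2)
            g = m_step_g(data, theta)
            _, _, r_prev = m_step_rates(g, r_prev)
            means = m_step_means(data, theta, previous=means)
            sigma2 = m_step_variance(data, theta, means, floor=1e-10)
            ll = log_likelihood_joint(data, g, means, sigma2)
            assert ll >= last - 1e-9
            last = ll

    def test_fixed_prior_em_is_monotone(self, small_dataset):
        """The inner EM at fixed mixture weights (profile stage) never
        decreases the conditional log-likelihood."""
        data = small_dataset
        g = chromatid_modes(0.3, 0.05)
        means = np.zeros(10)
        sigma2 = float(np.var(data.phenotype))
        last = -np.inf
        for _ in range(60):
            theta = e_step(data, g, means, sigma2)
            means = m_step_means(data, theta, previous=means)
            sigma2 = m_step_variance(data, theta, means, floor=1e-10)
            ll = log_likelihood(data, g, means, sigma2)
            assert ll >= last - 1e-9
            last = ll

    def test_r_count_update_is_stationary_at_fixed_point(self):
        """The expected-recombination-count update reproduces the implied r
        of the chromatid surface (consistency of the two r expressions)."""
        g = chromatid_modes(0.3, 0.17)
        counts = recombination_count_rows(0.17)
        joint = build_joint_table(g)
        assert (joint * counts).sum() / 2 == pytest.approx(0.17, abs=1e-12)


class TestAlphaIdentity:
    def test_alpha_equals_marker_dr_fraction_every_iteration(self, small_dataset):
        data = small_dataset
        observed = float(np.mean(data.marker < 4))
        g = chromatid_modes(0.3, 0.25)
        g = 0.98 * g + 0.02 / 9
        means = np.linspace(-1, 3, 10)
        sigma2 = float(np.var(data.phenotype))
        for _ in range(25):
            theta = e_step(data, g, means, sigma2)
            g = m_step_g(data, theta)
            alpha, _, _ = m_step_rates(g, 0.25)
            assert alpha == pytest.approx(observed, abs=1e-12)
            means = m_step_means(data, theta, previous=means)
            sigma2 = m_step_variance(data, theta, means, floor=1e-10)

    def test_fit_reports_observed_fraction(self, small_dataset):
        res = fit(small_dataset, FAST)
        assert res.alpha_hat == pytest.approx(
            float(np.mean(small_dataset.marker < 4)), abs=1e-12)
        dr_sum = res.g_hat[0] + res.g_hat[1] + res.g_hat[4] + res.g_hat[5]
        assert dr_sum == pytest.approx(res.alpha_hat, abs=1e-9)


class TestRecovery:
    def test_near_noiseless_limit(self, study_effects):
        config = SimulationConfig(n=400, alpha=0.3, r=0.05,
                                  effects=study_effects, h2=0.995, seed=21)
        data = simulate_dataset(config)
        res = fit(data, EMOptions())
        assert res.converged
        assert res.alpha_hat == pytest.approx(0.3, abs=0.06)
        assert res.r_hat == pytest.approx(0.05, abs=0.02)
        truth = effects_to_means(study_effects)
        assert np.allclose(res.means_hat, truth, atol=0.15)
        assert res.effects_hat.mu == pytest.approx(1.0, abs=0.05)

    def test_fix_r_pins_the_estimate(self, small_dataset):
        res = fit(small_dataset, EMOptions(fix_r=0.19, r_grid_step=0.1))
        assert res.r_hat == 0.19

    def test_modes_em_and_profile_agree_in_easy_case(self, study_effects):
        config = SimulationConfig(n=300, alpha=0.3, r=0.05,
                                  effects=study_effects, h2=0.99, seed=31)
        data = simulate_dataset(config)
        res_p = fit(data, EMOptions())
        res_e = fit(data, EMOptions(mode="em", max_iter=3000))
        assert res_p.r_hat == pytest.approx(res_e.r_hat, abs=0.02)
        assert res_p.alpha_hat == pytest.approx(res_e.alpha_hat, abs=1e-12)


class TestConstrainedFits:
    def test_nesting_never_exceeds_full_fit(self, small_dataset):
        full = fit(small_dataset, FAST)
        for kind in ("presence_null", "additive_null", "dominance_null"):
            res = fit_constrained(small_dataset, constraint_design(kind), FAST)
            assert res.loglik <= full.loglik + 1e-6

    def test_full_design_constraint_reproduces_fit(self, small_dataset):
        full = fit(small_dataset, FAST)
        res = fit_constrained(small_dataset, constraint_design("full"), FAST)
        assert res.loglik == pytest.approx(full.loglik, abs=1e-4)

    def test_additive_null_equalizes_homozygote_means(self, small_dataset):
        res = fit_constrained(small_dataset,
                              constraint_design("additive_null"), FAST)
        assert np.allclose(res.means_hat[:4], res.means_hat[0], atol=1e-8)
        assert abs(res.effects_hat.a1) < 1e-8

    def test_dominance_null_on_additive_data(self, study_effects):
        from tetraqtl.quantgen import QTLEffects
        eff = QTLEffects(mu=1.0, a1=0.6, a2=0.6, a3=0.6)
        config = SimulationConfig(n=300, alpha=0.3, r=0.05, effects=eff,
                                  h2=0.6, seed=13)
        data = simulate_dataset(config)
        full = fit(data, FAST)
        null = fit_constrained(data, constraint_design("dominance_null"), FAST)
        # nested true model: likelihood loss should be modest (chi2_6 scale)
        assert 2 * (full.loglik - null.loglik) < 30.0


class TestNoDoubleReductionModel:
    def test_drops_dr_individuals_with_warning(self, small_dataset):
        with pytest.warns(UserWarning, match="dropping"):
            res = fit(small_dataset, EMOptions(force_no_double_reduction=True,
                                               r_grid_step=0.1))
        assert res.n_dropped == int(np.sum(small_dataset.marker < 4))
        assert res.alpha_hat == 0.0
        assert np.isnan(res.means_hat[:4]).all()
        assert np.isfinite(res.means_hat[4:]).all()
        assert res.effects_hat is None

    def test_constrained_not_defined(self, small_dataset):
        with pytest.raises(ValueError):
            fit_constrained(small_dataset, constraint_design("additive_null"),
                            EMOptions(force_no_double_reduction=True))


class TestOptionValidation:
    def test_bad_options_rejected(self):
        with pytest.raises(ValueError):
            EMOptions(tol=0)
        with pytest.raises(ValueError):
            EMOptions(mode="bogus")
        with pytest.raises(ValueError):
            EMOptions(r_grid_step=0.4)
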